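"""Driver attribution and inference: ANOVA with compact letters, PCA
ordination summaries, Mantel tests, permutation random-forest importance,
and standardized observed-variable path analysis."""

from __future__ import annotations

import string
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceTable

# --------------------------------------------------------------------------
# one-way ANOVA + Tukey HSD with compact letter display
# --------------------------------------------------------------------------


@dataclass
class TukeyReport:
    f_statistic: float
    p_value: float
    alpha: float
    table: pd.DataFrame  # per group: mean, sd, n, letters
    pairwise: pd.DataFrame  # group1, group2, meandiff, p_adj, reject


def _insert_absorb(order: list, significant: set[frozenset]) -> dict:
    """Compact letter display by insert-and-absorb.

    ``order`` fixes letter precedence (first group tends to get 'a').
    Groups share a letter iff their pair is not in ``significant``.
    """
    columns: list[set] = [set(order)]
    for pair in significant:
        a, b = tuple(pair)
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            for new in (col - {a}, col - {b}):
                if not any(new <= other for other in columns):
                    columns.append(new)
            # absorb columns that became subsets of another
            columns = [
                c
                for i, c in enumerate(columns)
                if not any(
                    (c < d) or (c == d and i > j) for j, d in enumerate(columns)
                )
            ]
    columns.sort(key=lambda c: min(order.index(g) for g in c))
    letters = {g: "" for g in order}
    for letter, col in zip(string.ascii_lowercase, columns):
        for g in order:
            if g in col:
                letters[g] += letter
    return letters


def anova_tukey(
    values: pd.Series, groups: pd.Series, alpha: float = 0.05
) -> TukeyReport:
    """One-way ANOVA with all-pairs Tukey HSD and compact letters.

    Groups sharing a letter do not differ at the given alpha. Letters are
    assigned with 'a' anchored at the highest group mean.
    """
    values = pd.Series(values).astype(float)
    groups = pd.Series(groups).loc[values.index]
    by_group = {g: v.to_numpy() for g, v in values.groupby(groups)}
    if len(by_group) < 2:
        raise ValueError("need >= 2 groups")
    for g, v in by_group.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    if all(np.ptp(v) == 0 for v in by_group.values()):
        raise ValueError("zero within-group variance in every group")

    f_stat, p = stats.f_oneway(*by_group.values())
    hsd = pairwise_tukeyhsd(values.to_numpy(), groups.to_numpy(), alpha=alpha)
    pairwise = pd.DataFrame(
        hsd.summary().data[1:],
        columns=[str(c) for c in hsd.summary().data[0]],
    )
    significant = {
        frozenset((row["group1"], row["group2"]))
        for _, row in pairwise.iterrows()
        if bool(row["reject"])
    }
    order = sorted(by_group, key=lambda g: -by_group[g].mean())
    letters = _insert_absorb(order, significant)
    table = pd.DataFrame(
        {
            "mean": {g: v.mean() for g, v in by_group.items()},
            "sd": {g: v.std(ddof=1) for g, v in by_group.items()},
            "n": {g: len(v) for g, v in by_group.items()},
            "letters": letters,
        }
    ).loc[list(by_group)]
    return TukeyReport(float(f_stat), float(p), alpha, table, pairwise)


# --------------------------------------------------------------------------
# PCA ordination summary
# --------------------------------------------------------------------------


def pca_summary(table) -> tuple[pd.DataFrame, pd.Series]:
    """PCA of per-sample relative abundances (centered).

    Returns (sample scores, % variance explained per axis); the percentages
    sum to 100 across all returned axes.
    """
    if isinstance(table, AbundanceTable):
        data = table.relative_abundance()
    else:
        data = pd.DataFrame(table).astype(float)
    if data.shape[0] < 3:
        raise ValueError("need >= 3 samples for ordination")
    pca = PCA(n_components=min(data.shape[0], data.shape[1]))
    scores = pca.fit_transform(data.to_numpy())
    axes = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=data.index, columns=axes),
        pd.Series(100.0 * pca.explained_variance_ratio_, index=axes,
                  name="pct_variance"),
    )


# --------------------------------------------------------------------------
# Mantel test
# --------------------------------------------------------------------------


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    seed: int
    n_samples: int


def bray_curtis_distance(table: AbundanceTable) -> pd.DataFrame:
    """Bray-Curtis distances between samples of a count table."""
    d = squareform(pdist(table.counts.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


def euclidean_distance(data: pd.DataFrame, zscore: bool = True) -> pd.DataFrame:
    """Euclidean distances between rows, by default after z-scoring columns."""
    x = pd.DataFrame(data).astype(float)
    if zscore:
        sd = x.std(ddof=1).replace(0.0, 1.0)
        x = (x - x.mean()) / sd
    d = squareform(pdist(x.to_numpy()))
    return pd.DataFrame(d, index=x.index, columns=x.index)


def _check_distance(d: pd.DataFrame, name: str) -> np.ndarray:
    m = d.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} is not square")
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValueError(f"{name} is not symmetric")
    if not np.allclose(np.diag(m), 0.0):
        raise ValueError(f"{name} has a nonzero diagonal")
    return m


def mantel(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
    method: str = "spearman",
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    r correlates the off-diagonal distance vectors (Spearman by default);
    the one-sided p is (1 + #{permuted r >= observed r}) / (1 + B), with
    rows and columns of ``d2`` permuted jointly.
    """
    d1, d2 = pd.DataFrame(d1), pd.DataFrame(d2)
    if set(d1.index) != set(d2.index):
        raise ValueError("distance matrices cover different samples")
    d2 = d2.loc[d1.index, d1.index]
    m1 = _check_distance(d1, "d1")
    m2 = _check_distance(d2, "d2")
    n = m1.shape[0]
    if n < 5:
        raise ValueError("need >= 5 samples for a Mantel test")
    iu = np.triu_indices(n, k=1)
    v1, v2 = m1[iu], m2[iu]
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("zero-variance distance vector")
    if method == "spearman":
        v1 = stats.rankdata(v1)
        rank = stats.rankdata
    elif method == "pearson":
        rank = lambda x: x  # noqa: E731
    else:
        raise ValueError(f"unknown method {method!r}")

    def corr(a, b):
        return float(np.corrcoef(a, b)[0, 1])

    r_obs = corr(v1, rank(v2))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        v2p = m2[np.ix_(perm, perm)][iu]
        if corr(v1, rank(v2p)) >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return MantelResult(r_obs, p, n_permutations, seed, n)


def mantel_grid(
    indicators: pd.DataFrame,
    communities: dict[str, AbundanceTable],
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Mantel tests of every indicator against every community distance.

    Each indicator column becomes a z-scored Euclidean distance; each
    community a Bray-Curtis distance. BH adjustment is applied across the
    whole property x community grid.
    """
    rows = []
    comm_dists = {k: bray_curtis_distance(t) for k, t in communities.items()}
    for j, indicator in enumerate(indicators.columns):
        d_ind = euclidean_distance(indicators[[indicator]])
        for k, (kingdom, d_comm) in enumerate(comm_dists.items()):
            sub_seed = seed + 7919 * j + 104729 * k
            res = mantel(d_ind, d_comm, n_permutations, seed=sub_seed)
            rows.append(
                {
                    "indicator": indicator,
                    "community": kingdom,
                    "r": res.r,
                    "p": res.p,
                    "n_permutations": n_permutations,
                    "seed": sub_seed,
                }
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


# --------------------------------------------------------------------------
# permutation random-forest importance
# --------------------------------------------------------------------------


class PermutationForestImportance:
    """Random-forest regression with cross-validated permutation importance.

    A predictor's importance is the mean relative increase (%) in held-out
    squared error when its values are permuted, averaged over K folds and
    ``n_repeats`` permutations per fold. Held-out (fold) predictions play
    the role of out-of-bag predictions so that uninformative predictors
    score near zero instead of inheriting training-set overfit.

    Attributes
    ----------
    importances_ : pandas.Series
        Mean % increase in squared error, per predictor.
    ranks_ : pandas.Series
        Dense ranks, 1 = most important.
    r2_ : float
        Cross-validated R^2 of the unpermuted model.
    """

    def __init__(self, n_trees: int = 500, n_repeats: int = 10,
                 n_folds: int = 3, seed: int = 0):
        self.n_trees = n_trees
        self.n_repeats = n_repeats
        self.n_folds = n_folds
        self.seed = seed

    def get_params(self, deep=True):
        return {
            "n_trees": self.n_trees,
            "n_repeats": self.n_repeats,
            "n_folds": self.n_folds,
            "seed": self.seed,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X).astype(float)
        y = pd.Series(y).loc[X.index].astype(float)
        n, p = X.shape
        if n < 10:
            raise ValueError("need >= 10 observations")
        if p < 2:
            raise ValueError("need >= 2 predictors")
        if np.ptp(y.to_numpy()) == 0:
            raise ValueError("constant response")
        rng = np.random.default_rng(self.seed)
        kf = KFold(n_splits=self.n_folds, shuffle=True, random_state=self.seed)
        increase = np.zeros(p)
        sse_base, sse_null = 0.0, 0.0
        xv, yv = X.to_numpy(), y.to_numpy()
        for train, test in kf.split(xv):
            model = RandomForestRegressor(
                n_estimators=self.n_trees, random_state=self.seed
            ).fit(xv[train], yv[train])
            pred = model.predict(xv[test])
            mse_base = float(np.mean((yv[test] - pred) ** 2))
            sse_base += float(np.sum((yv[test] - pred) ** 2))
            sse_null += float(np.sum((yv[test] - yv[train].mean()) ** 2))
            for j in range(p):
                bump = 0.0
                for _ in range(self.n_repeats):
                    xp = xv[test].copy()
                    xp[:, j] = rng.permutation(xp[:, j])
                    mse = float(np.mean((yv[test] - model.predict(xp)) ** 2))
                    bump += (mse - mse_base) / max(mse_base, 1e-12)
                increase[j] += bump / self.n_repeats
        self.importances_ = pd.Series(
            100.0 * increase / self.n_folds, index=X.columns, name="importance_pct"
        )
        self.ranks_ = self.importances_.rank(ascending=False, method="first").astype(int)
        self.r2_ = 1.0 - sse_base / sse_null
        self.model_ = RandomForestRegressor(
            n_estimators=self.n_trees, random_state=self.seed
        ).fit(xv, yv)
        return self

    def report(self) -> pd.DataFrame:
        if not hasattr(self, "importances_"):
            raise RuntimeError("PermutationForestImportance is not fitted")
        return pd.DataFrame(
            {"importance_pct": self.importances_, "rank": self.ranks_}
        ).sort_values("rank")


def rf_importance(
    predictors: pd.DataFrame,
    response,
    n_trees: int = 500,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance report (predictor, importance %, rank)."""
    est = PermutationForestImportance(
        n_trees=n_trees, n_repeats=n_repeats, seed=seed
    ).fit(predictors, response)
    out = est.report()
    out["cv_r2"] = est.r2_
    out["seed"] = seed
    return out


# --------------------------------------------------------------------------
# standardized path analysis
# --------------------------------------------------------------------------


class PathAnalysis:
    """Observed-variable acyclic path model with standardized coefficients.

    Each endogenous variable is regressed (OLS) on its parents after all
    variables are z-scored, so coefficients are standardized direct effects.
    This is the observed-variable analogue of a structural equation model
    without latent constructs or global fit indices.

    Parameters
    ----------
    edges : iterable of (parent, child)
        Directed edges; the graph must be acyclic.

    Attributes
    ----------
    coefficients_ : pandas.DataFrame
        parent, child, coefficient, standard error, p value.
    r2_ : pandas.Series
        R^2 per endogenous variable.
    """

    def __init__(self, edges):
        self.edges = list(edges)

    def get_params(self, deep=True):
        return {"edges": self.edges}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, data: pd.DataFrame):
        g = nx.DiGraph(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("path model is cyclic")
        data = pd.DataFrame(data).astype(float)
        missing = [v for v in g.nodes if v not in data.columns]
        if missing:
            raise ValueError(f"variables absent from data: {missing}")
        z = (data - data.mean()) / data.std(ddof=1)
        n = len(z)
        rows, r2 = [], {}
        for child in nx.topological_sort(g):
            parents = sorted(g.predecessors(child))
            if not parents:
                continue
            if n <= len(parents) + 2:
                raise ValueError(
                    f"too few observations to fit {child!r} on {len(parents)} parents"
                )
            xmat = z[parents].to_numpy()
            if np.linalg.cond(xmat) > 1e8:
                raise ValueError(f"collinear parents for {child!r}: {parents}")
            yvec = z[child].to_numpy()
            beta, _, _, _ = np.linalg.lstsq(xmat, yvec, rcond=None)
            resid = yvec - xmat @ beta
            dof = n - len(parents)
            sigma2 = float(resid @ resid) / dof
            cov = sigma2 * np.linalg.inv(xmat.T @ xmat)
            se = np.sqrt(np.diag(cov))
            tvals = beta / se
            pvals = 2 * stats.t.sf(np.abs(tvals), dof)
            r2[child] = 1.0 - float(resid @ resid) / float(yvec @ yvec)
            rows += [
                {
                    "parent": par,
                    "child": child,
                    "coefficient": float(b),
                    "se": float(s),
                    "p": float(pv),
                }
                for par, b, s, pv in zip(parents, beta, se, pvals)
            ]
        self.graph_ = g
        self.coefficients_ = pd.DataFrame(rows)
        self.r2_ = pd.Series(r2, name="r2")
        return self


def path_analysis(data: pd.DataFrame, edges) -> PathAnalysis:
    """Fit a standardized observed-variable path model."""
    return PathAnalysis(edges).fit(data)
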