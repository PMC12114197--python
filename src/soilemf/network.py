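"""Signed Spearman co-occurrence networks and topology summaries.

Edges connect taxon pairs whose Spearman correlation passes both a
magnitude threshold and a Benjamini-Hochberg adjusted p threshold; edge
sign is the correlation sign and edge weight its magnitude. The topology
battery reports node/link counts, the positive-link percentage, average
degree 2L/N, graph density 2L/(N(N-1)), and Newman modularity of a greedy
modularity-maximizing partition on the unsigned (|rho|-weighted) graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceTable

DEFAULT_RHO_THRESHOLD = 0.6
DEFAULT_P_THRESHOLD = 0.05


def filter_taxa(
    table: AbundanceTable, min_prevalence: float = 0.2, top_n: int | None = None
) -> AbundanceTable:
    """Keep taxa present in >= ``min_prevalence`` of samples, then the
    ``top_n`` most abundant; original column order is preserved."""
    if not 0 < min_prevalence <= 1:
        if min_prevalence != 0:
            raise ValueError("min_prevalence must be in (0, 1] (or 0 to disable)")
    prevalence = (table.counts > 0).mean(axis=0)
    keep = prevalence.index[prevalence >= min_prevalence]
    if top_n is not None and len(keep) > top_n:
        totals = table.counts[keep].sum(axis=0)
        top = set(totals.nlargest(top_n).index)
        keep = [t for t in keep if t in top]
    if len(keep) == 0:
        raise ValueError(
            "no taxa survive filtering; lower min_prevalence or raise top_n"
        )
    return AbundanceTable(table.counts[list(keep)], table.kingdom, table.taxonomy)


def spearman_matrix(table: AbundanceTable) -> pd.DataFrame:
    """All pairwise Spearman correlations with BH-adjusted p values.

    Ties are handled by average ranks; two-sided p values come from the
    t approximation. Constant taxa are removed with a warning. Returns a
    tidy frame (taxon_a, taxon_b, rho, p, p_adj) over unordered pairs.
    """
    counts = table.counts
    if counts.shape[0] < 4:
        raise ValueError("need >= 4 samples for rank correlation")
    constant = counts.columns[counts.nunique(axis=0) <= 1]
    if len(constant):
        warnings.warn(
            f"removing {len(constant)} constant taxa before correlation",
            UserWarning,
            stacklevel=2,
        )
        counts = counts.drop(columns=constant)
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 non-constant taxa")
    if counts.shape[1] == 2:
        r, pv = stats.spearmanr(counts.iloc[:, 0], counts.iloc[:, 1])
        rho = np.array([[1.0, r], [r, 1.0]])
        p = np.array([[0.0, pv], [pv, 0.0]])
    else:
        rho, p = stats.spearmanr(counts.to_numpy(), axis=0)
    taxa = list(counts.columns)
    iu = np.triu_indices(len(taxa), k=1)
    out = pd.DataFrame(
        {
            "taxon_a": np.asarray(taxa)[iu[0]],
            "taxon_b": np.asarray(taxa)[iu[1]],
            "rho": rho[iu],
            "p": p[iu],
        }
    )
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def build_network(
    correlations: pd.DataFrame,
    rho_threshold: float = DEFAULT_RHO_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> nx.Graph:
    """Signed network from a correlation frame.

    An edge is kept when |rho| >= ``rho_threshold`` and adjusted
    p < ``p_threshold``. Only incident nodes enter the node set.
    """
    if not (0 < rho_threshold <= 1 and 0 < p_threshold <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    g = nx.Graph(rho_threshold=rho_threshold, p_threshold=p_threshold)
    # small tolerance so a floating-point rho of 1 - 1e-16 passes threshold 1
    passing = correlations[
        (correlations["rho"].abs() >= rho_threshold - 1e-12)
        & (correlations["p_adj"] < p_threshold)
    ]
    for row in passing.itertuples(index=False):
        g.add_edge(
            row.taxon_a,
            row.taxon_b,
            rho=float(row.rho),
            sign=1 if row.rho > 0 else -1,
            weight=abs(float(row.rho)),
            p_adj=float(row.p_adj),
        )
    return g


def ratio_metrics(nodes: int, links: int, positive_links: int) -> dict[str, float]:
    """Ratio topology metrics from raw counts.

    positive-link % = 100 * positive/links; average degree = 2L/N;
    graph density = 2L/(N(N-1)). NaN where undefined.
    """
    out = {
        "positive_pct": 100.0 * positive_links / links if links else float("nan"),
        "average_degree": 2.0 * links / nodes if nodes else float("nan"),
        "graph_density": (
            2.0 * links / (nodes * (nodes - 1)) if nodes > 1 else float("nan")
        ),
    }
    return out


@dataclass
class TopologySummary:
    nodes: int
    links: int
    positive_links: int
    negative_links: int
    positive_pct: float
    average_degree: float
    graph_density: float
    modularity: float
    communities: list[frozenset] = field(default_factory=list)

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "Nodes": self.nodes,
                "Links": self.links,
                "Positive links": self.positive_links,
                "Negative links": self.negative_links,
                "Positive links%": self.positive_pct,
                "Average degree": self.average_degree,
                "Modularity": self.modularity,
                "Graph density": self.graph_density,
            }
        )


def topology(network: nx.Graph, seed: int = 0) -> TopologySummary:
    """Topology battery for one signed network.

    Communities come from greedy modularity maximization on |rho| weights
    (deterministic; ``seed`` is accepted for interface stability). An empty
    network yields zero counts and NaN ratio metrics.
    """
    n = network.number_of_nodes()
    links = network.number_of_edges()
    pos = sum(1 for _, _, d in network.edges(data=True) if d.get("sign", 1) > 0)
    metrics = ratio_metrics(n, links, pos)
    if links == 0:
        return TopologySummary(
            n, 0, 0, 0, metrics["positive_pct"], metrics["average_degree"],
            metrics["graph_density"], float("nan"),
        )
    comms = nx.community.greedy_modularity_communities(network, weight="weight")
    q = nx.community.modularity(network, comms, weight="weight")
    return TopologySummary(
        nodes=n,
        links=links,
        positive_links=pos,
        negative_links=links - pos,
        positive_pct=metrics["positive_pct"],
        average_degree=metrics["average_degree"],
        graph_density=metrics["graph_density"],
        modularity=q,
        communities=[frozenset(c) for c in comms],
    )


class CooccurrenceNetwork:
    """Estimator building a signed co-occurrence network from counts.

    Parameters
    ----------
    min_prevalence, top_n :
        Taxon pre-filter (presence fraction; most-abundant cap).
    rho_threshold, p_threshold :
        Edge criteria: |Spearman rho| >= rho_threshold and BH-adjusted
        p < p_threshold.
    seed : int
        Passed to the community step (the default algorithm is
        deterministic).

    Attributes
    ----------
    correlations_ : pandas.DataFrame
        Tidy pairwise correlation results.
    graph_ : networkx.Graph
    topology_ : TopologySummary
    """

    def __init__(
        self,
        min_prevalence: float = 0.2,
        top_n: int | None = None,
        rho_threshold: float = DEFAULT_RHO_THRESHOLD,
        p_threshold: float = DEFAULT_P_THRESHOLD,
        seed: int = 0,
    ):
        self.min_prevalence = min_prevalence
        self.top_n = top_n
        self.rho_threshold = rho_threshold
        self.p_threshold = p_threshold
        self.seed = seed

    def get_params(self, deep=True):
        return {
            "min_prevalence": self.min_prevalence,
            "top_n": self.top_n,
            "rho_threshold": self.rho_threshold,
            "p_threshold": self.p_threshold,
            "seed": self.seed,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        if not isinstance(X, AbundanceTable):
            X = AbundanceTable(pd.DataFrame(X))
        filtered = filter_taxa(X, self.min_prevalence, self.top_n)
        self.correlations_ = spearman_matrix(filtered)
        self.graph_ = build_network(
            self.correlations_, self.rho_threshold, self.p_threshold
        )
        self.topology_ = topology(self.graph_, seed=self.seed)
        return self

    def edge_list(self) -> pd.DataFrame:
        if not hasattr(self, "graph_"):
            raise RuntimeError("CooccurrenceNetwork is not fitted")
        rows = [
            {
                "source": u,
                "target": v,
                "rho": d["rho"],
                "sign": "+" if d["sign"] > 0 else "-",
                "p_adj": d["p_adj"],
            }
            for u, v, d in self.graph_.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "rho", "sign", "p_adj"])


def per_treatment_networks(
    table: AbundanceTable,
    metadata: pd.Series,
    min_prevalence: float = 0.2,
    top_n: int | None = None,
    rho_threshold: float = DEFAULT_RHO_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    seed: int = 0,
) -> dict[str, tuple[nx.Graph, TopologySummary]]:
    """One network + summary per treatment (treatment order preserved).

    Treatments with fewer than 4 samples are skipped with a warning.
    """
    missing = [s for s in table.sample_ids if s not in metadata.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    out: dict[str, tuple[nx.Graph, TopologySummary]] = {}
    for treatment in pd.unique(metadata.loc[table.sample_ids]):
        samples = [s for s in table.sample_ids if metadata[s] == treatment]
        if len(samples) < 4:
            warnings.warn(
                f"treatment {treatment!r} has {len(samples)} samples (<4); skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        est = CooccurrenceNetwork(
            min_prevalence, top_n, rho_threshold, p_threshold, seed
        ).fit(table.subset_samples(samples))
        out[treatment] = (est.graph_, est.topology_)
    return out


def topology_frame(
    summaries: dict[str, TopologySummary] | dict[str, tuple[nx.Graph, TopologySummary]]
) -> pd.DataFrame:
    """Metric rows x treatment columns summary table."""
    cols = {}
    for label, value in summaries.items():
        summary = value[1] if isinstance(value, tuple) else value
        cols[label] = summary.as_series()
    return pd.DataFrame(cols)
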