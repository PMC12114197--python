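"""Alpha-diversity and richness estimators from count data.

Shannon entropy (natural log), Simpson dominance (sum of squared
proportions, which *decreases* as diversity rises), bias-corrected Chao1,
and ACE with the conventional rare-taxon cutoff of 10. All are computed
directly from their frequency-count definitions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import AbundanceTable

INDEX_NAMES = ("observed", "shannon", "simpson", "chao1", "ace")


def _as_counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("expected a 1-D vector of counts for one sample")
    if (c < 0).any() or not np.allclose(c, np.round(c)):
        raise ValueError("counts must be nonnegative integers")
    if c.sum() == 0:
        raise ValueError("sample has no observations")
    return c


def shannon(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i, in nats."""
    c = _as_counts(counts)
    p = c[c > 0] / c.sum()
    return float(-(p * np.log(p)).sum())


def simpson(counts) -> float:
    """Simpson dominance D = sum p_i^2 (1 = single taxon, 1/S = uniform)."""
    c = _as_counts(counts)
    p = c / c.sum()
    return float((p**2).sum())


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness from singleton/doubleton frequencies.

    Bias-corrected form S_obs + F1(F1-1)/(2(F2+1)) by default; the classic
    form S_obs + F1^2/(2 F2) is available but undefined at F2 = 0.
    """
    c = _as_counts(counts)
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        raise ZeroDivisionError("classic Chao1 undefined with no doubletons")
    return s_obs + f1**2 / (2.0 * f2)


def ace(counts, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator (ACE).

    Taxa with counts <= ``rare_cutoff`` form the rare group. With sample
    coverage C = 1 - F1/N_rare and squared coefficient of variation
    gamma^2 (floored at 0),

        ACE = S_abund + S_rare/C + (F1/C) * gamma^2.

    When every rare taxon is a singleton, C = 0 and the estimator is
    undefined; the bias-corrected Chao1 of the sample is returned instead.
    """
    c = _as_counts(counts)
    c = c[c > 0]
    rare = c[c <= rare_cutoff]
    s_abund = int((c > rare_cutoff).sum())
    s_rare = len(rare)
    if s_rare == 0:
        return float(s_abund)
    n_rare = rare.sum()
    f1 = int((rare == 1).sum())
    coverage = 1.0 - f1 / n_rare
    if coverage == 0.0:
        return chao1(counts)
    ks = np.arange(1, rare_cutoff + 1)
    fk = np.array([(rare == k).sum() for k in ks])
    gamma2 = (s_rare / coverage) * (ks * (ks - 1) * fk).sum() / (
        n_rare * (n_rare - 1)
    ) - 1.0
    gamma2 = max(gamma2, 0.0)
    return s_abund + s_rare / coverage + (f1 / coverage) * gamma2


def _one_sample(counts, rare_cutoff: int) -> dict[str, float]:
    c = _as_counts(counts)
    return {
        "observed": float((c > 0).sum()),
        "shannon": shannon(c),
        "simpson": simpson(c),
        "chao1": chao1(c),
        "ace": ace(c, rare_cutoff=rare_cutoff),
    }


def diversity_table(
    table: AbundanceTable,
    metadata: pd.Series | None = None,
    rare_cutoff: int = 10,
) -> pd.DataFrame:
    """All indices per sample; joins treatment metadata when given."""
    rows = {}
    for sample in table.sample_ids:
        try:
            rows[sample] = _one_sample(table.counts.loc[sample], rare_cutoff)
        except ValueError as exc:
            raise ValueError(f"sample {sample!r}: {exc}") from exc
    out = pd.DataFrame.from_dict(rows, orient="index")
    if metadata is not None:
        out.insert(0, "treatment", metadata.reindex(out.index))
    return out


class AlphaDiversity:
    """Per-sample diversity indices as an sklearn-style transformer.

    ``transform`` maps an :class:`AbundanceTable` (or samples x taxa
    DataFrame) to a samples x indices DataFrame. Stateless; ``fit`` exists
    for pipeline compatibility.
    """

    def __init__(self, rare_cutoff: int = 10):
        self.rare_cutoff = rare_cutoff

    def get_params(self, deep=True):
        return {"rare_cutoff": self.rare_cutoff}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> pd.DataFrame:
        if not isinstance(X, AbundanceTable):
            X = AbundanceTable(pd.DataFrame(X))
        return diversity_table(X, rare_cutoff=self.rare_cutoff)

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.transform(X)
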