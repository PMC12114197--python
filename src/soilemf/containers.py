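"""In-memory containers shared across the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class AbundanceTable:
    """Count table for one kingdom, oriented samples x taxa.

    Parameters
    ----------
    counts : pandas.DataFrame
        Nonnegative integer counts; index = sample ids, columns = taxon ids.
    kingdom : str
        ``"bacteria"`` or ``"fungi"``.
    taxonomy : dict, optional
        Mapping taxon id -> phylum.
    """

    counts: pd.DataFrame
    kingdom: str = "bacteria"
    taxonomy: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        c = self.counts.copy(deep=False)
        c.index = c.index.rename("sample")
        c.columns = c.columns.rename(None)
        self.counts = c
        if c.index.has_duplicates:
            raise ValueError("duplicate sample ids in abundance table")
        if c.columns.has_duplicates:
            raise ValueError("duplicate taxon ids in abundance table")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("abundance table must be numeric")
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative count at sample {c.index[bad[0]]!r}, "
                f"taxon {c.columns[bad[1]]!r}"
            )
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("abundance table must hold integer counts")
        if (vals.sum(axis=1) == 0).any():
            empty = c.index[vals.sum(axis=1) == 0][0]
            raise ValueError(f"sample {empty!r} has no positive counts")

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        return AbundanceTable(
            self.counts.loc[list(sample_ids)], self.kingdom, self.taxonomy
        )

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample proportions (rows sum to 1)."""
        return self.counts.div(self.counts.sum(axis=1), axis=0)


def validate_indicator_matrix(x: pd.DataFrame) -> pd.DataFrame:
    """Validate a plots x indicators measurement matrix.

    Requires finite numeric values, unique plot and indicator labels,
    and at least two plots (min-max standardization is degenerate with one).
    """
    if x.index.has_duplicates:
        raise ValueError("duplicate plot ids in indicator matrix")
    if x.columns.has_duplicates:
        raise ValueError("duplicate indicator names in indicator matrix")
    if x.shape[0] < 2:
        raise ValueError("indicator matrix needs at least 2 plots")
    vals = x.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("indicator matrix contains non-finite values")
    return x.rename_axis(index="plot", columns=None)
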