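"""Ecosystem-function (EF) and multifunctionality (EMF) indices.

Each indicator column is min-max standardized across all plots,
``f_ij = (X_ij - min_j) / (max_j - min_j)``, so every retained column spans
[0, 1]. A function-group EF score is the per-plot mean of its member
columns (the carbon nutrients-and-storage group EF-C defaults to
SOC/MBC/EOC/DOC), and the averaging-method EMF is the per-plot mean of all
retained standardized columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import validate_indicator_matrix

DEFAULT_EFC_GROUP = ("SOC", "MBC", "EOC", "DOC")


@dataclass
class FunctionGroupSpec:
    """Grouping and orientation of indicators.

    ``directions`` maps indicator -> +1/-1; -1 indicators are negated before
    standardization (so "less is better" measurements contribute positively).
    ``constant_policy`` controls columns with zero range: ``drop`` excludes
    them (with a warning), ``zero`` sets them to 0, ``error`` raises.
    """

    groups: dict[str, list[str]] = field(
        default_factory=lambda: {"EF-C": list(DEFAULT_EFC_GROUP)}
    )
    directions: dict[str, int] = field(default_factory=dict)
    constant_policy: str = "drop"

    def direction(self, indicator: str) -> int:
        return self.directions.get(indicator, 1)

    def validate_against(self, columns) -> None:
        cols = set(columns)
        for group, members in self.groups.items():
            missing = [m for m in members if m not in cols]
            if missing:
                raise ValueError(
                    f"group {group!r} references unknown indicators: {missing}"
                )
        if self.constant_policy not in ("drop", "zero", "error"):
            raise ValueError(f"unknown constant_policy {self.constant_policy!r}")


@dataclass
class EMFResult:
    standardized: pd.DataFrame
    ef: pd.DataFrame  # plots x groups
    emf: pd.Series
    dropped_indicators: list[str]


class MultifunctionalityIndex:
    """Min-max standardizer with EF/EMF scoring (sklearn-style transformer).

    Parameters
    ----------
    groups : dict, optional
        Mapping group name -> member indicators. Defaults to the carbon
        storage group ``EF-C`` = (SOC, MBC, EOC, DOC); groups whose members
        are absent from the fitted matrix are ignored at scoring time only
        if empty after drops would raise, see `compute_ef`.
    directions : dict, optional
        Indicator -> +1/-1 orientation (default +1 for all).
    constant_policy : {"drop", "zero", "error"}
        Handling of zero-range columns.

    Attributes
    ----------
    min_, max_ : pandas.Series
        Column extrema of the (direction-adjusted) training matrix.
    dropped_indicators_ : list of str
        Constant columns excluded under the ``drop`` policy.
    standardized_, ef_, emf_ :
        Scores for the fitted matrix.
    """

    def __init__(self, groups=None, directions=None, constant_policy="drop"):
        self.groups = groups
        self.directions = directions
        self.constant_policy = constant_policy

    def get_params(self, deep=True):
        return {
            "groups": self.groups,
            "directions": self.directions,
            "constant_policy": self.constant_policy,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _spec(self) -> FunctionGroupSpec:
        kwargs = {"constant_policy": self.constant_policy}
        if self.groups is not None:
            kwargs["groups"] = {g: list(m) for g, m in self.groups.items()}
        if self.directions is not None:
            kwargs["directions"] = dict(self.directions)
        return FunctionGroupSpec(**kwargs)

    def fit(self, X: pd.DataFrame, y=None):
        X = validate_indicator_matrix(pd.DataFrame(X))
        spec = self._spec()
        spec.validate_against(X.columns)
        signs = pd.Series(
            {c: float(spec.direction(c)) for c in X.columns}, dtype=float
        )
        oriented = X * signs

        lo, hi = oriented.min(axis=0), oriented.max(axis=0)
        constant = list(X.columns[(hi - lo) == 0])
        dropped: list[str] = []
        if constant:
            if spec.constant_policy == "error":
                raise ValueError(f"constant indicator columns: {constant}")
            if spec.constant_policy == "drop":
                warnings.warn(
                    f"dropping constant indicator columns: {constant}",
                    UserWarning,
                    stacklevel=2,
                )
                dropped = constant

        self.spec_ = spec
        self.signs_ = signs
        self.min_, self.max_ = lo, hi
        self.dropped_indicators_ = dropped
        self.feature_names_in_ = list(X.columns)
        self.standardized_ = self.transform(X)
        self.ef_ = self._ef_frame(self.standardized_)
        self.emf_ = self.standardized_.mean(axis=1).rename("EMF")
        if self.standardized_.shape[1] == 0:
            raise ValueError("all indicators dropped; EMF undefined")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check_fitted()
        X = pd.DataFrame(X)
        if list(X.columns) != self.feature_names_in_:
            X = X.loc[:, self.feature_names_in_]
        oriented = X * self.signs_
        rng = self.max_ - self.min_
        out = (oriented - self.min_).div(rng.where(rng != 0, 1.0))
        if self.spec_.constant_policy == "zero":
            out.loc[:, rng == 0] = 0.0
        keep = [c for c in out.columns if c not in self.dropped_indicators_]
        return out[keep].rename_axis("plot")

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).standardized_

    def _ef_frame(self, standardized: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        for group, members in self.spec_.groups.items():
            retained = [m for m in members if m in standardized.columns]
            if not retained:
                raise ValueError(
                    f"group {group!r} empty after dropping constant indicators"
                )
            cols[group] = standardized[retained].mean(axis=1)
        return pd.DataFrame(cols, index=standardized.index)

    def result(self) -> EMFResult:
        self._check_fitted()
        return EMFResult(
            self.standardized_, self.ef_, self.emf_, list(self.dropped_indicators_)
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "min_"):
            raise RuntimeError("MultifunctionalityIndex is not fitted")


def standardize_indicators(
    x: pd.DataFrame, spec: FunctionGroupSpec | None = None
) -> pd.DataFrame:
    """Min-max standardize each indicator column across plots."""
    spec = spec or FunctionGroupSpec(groups={})
    est = MultifunctionalityIndex(
        groups=spec.groups, directions=spec.directions,
        constant_policy=spec.constant_policy,
    )
    return est.fit(x).standardized_


def compute_ef(standardized: pd.DataFrame, group: list[str]) -> pd.Series:
    """Per-plot EF: mean of the group's standardized indicator columns."""
    retained = [g for g in group if g in standardized.columns]
    if not retained:
        raise ValueError(f"EF group empty or absent from matrix: {list(group)}")
    return standardized[retained].mean(axis=1)


def compute_emf(
    standardized: pd.DataFrame, metadata: pd.Series | None = None
) -> pd.Series | tuple[pd.Series, pd.Series]:
    """Averaging-method EMF: per-plot mean over all retained indicators.

    With ``metadata`` (sample -> treatment), also returns per-treatment means.
    """
    if standardized.shape[1] == 0:
        raise ValueError("no retained indicators; EMF undefined")
    emf = standardized.mean(axis=1).rename("EMF")
    if metadata is None:
        return emf
    return emf, emf.groupby(metadata.loc[emf.index]).mean()


def multifunctionality(
    x: pd.DataFrame, spec: FunctionGroupSpec | None = None
) -> EMFResult:
    """One-shot standardize + EF + EMF on a plots x indicators matrix."""
    spec = spec or FunctionGroupSpec()
    est = MultifunctionalityIndex(
        groups=spec.groups, directions=spec.directions,
        constant_policy=spec.constant_policy,
    )
    return est.fit(x).result()
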