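"""Core data structures for Treatment-Measured-Response (TMR) studies.

A TMR study is a collection of *variable groups*: blocks of numeric variables
measured over a common set of samples.  Each group plays one of three roles:

``treatment``
    experimenter-controlled or fixed covariates (binary treatment indicators,
    weight, ...) — always predictors;
``measured``
    omics layers (16S taxa, metabolites, gene expression) — may act as both
    predictor and response;
``response``
    clinical outcome variables (lung-function baselines and dose-response
    slopes) — always responses.

This module defines :class:`VariableGroup` and :class:`TMRDataset`, alignment
of groups onto their common samples, and the derivation of response features
(baseline and slope) from methacholine dose-response series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    InsufficientDataError,
    ParameterError,
    ValidationError,
)

logger = logging.getLogger(__name__)

ROLES = ("treatment", "measured", "response")

#: column-name convention for dose-response series: ``<parameter>@<dose>``
DOSE_SEPARATOR = "@"


@dataclass
class VariableGroup:
    """One named block of variables (samples x variables).

    Parameters
    ----------
    name:
        Short group label, e.g. ``"16S_DNA"`` or ``"cecum_metabolites"``.
    role:
        One of ``"treatment"``, ``"measured"``, ``"response"``.
    data:
        Numeric table with sample identifiers as the index and variable names
        as columns.
    meta:
        Free-form annotations.  Recognised keys include ``compositional``
        (bool), ``units`` (e.g. ``"counts"``, ``"relative_abundance"``,
        ``"alr"``) and ``dose_response`` (bool, response series columns use
        the ``<parameter>@<dose>`` convention).
    """

    name: str
    role: str
    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValidationError(
                f"group {self.name!r}: role must be one of {ROLES}, got {self.role!r}"
            )
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"group {self.name!r}: duplicate sample ids {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValidationError(f"group {self.name!r}: duplicate variable names {dupes}")
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_variables(self) -> int:
        return self.data.shape[1]

    def restrict(self, samples) -> "VariableGroup":
        """Row-subset and row-order the group to ``samples`` (strict lookup)."""
        missing = [s for s in samples if s not in self.data.index]
        if missing:
            raise AlignmentError(
                f"group {self.name!r}: samples {missing} not present"
            )
        return replace(self, data=self.data.loc[list(samples)].copy(), meta=dict(self.meta))

    def dropna_samples(self) -> "VariableGroup":
        """Drop samples with any missing value (complete-case restriction)."""
        clean = self.data.dropna(axis=0, how="any")
        n_dropped = self.data.shape[0] - clean.shape[0]
        if n_dropped:
            logger.info(
                "group %r: dropped %d sample(s) with missing values", self.name, n_dropped
            )
        return replace(self, data=clean.copy(), meta=dict(self.meta))


@dataclass
class TMRDataset:
    """Sample-aligned collection of variable groups."""

    groups: list[VariableGroup]
    sample_index: list[str]

    def by_role(self, role: str) -> list[VariableGroup]:
        if role not in ROLES:
            raise ParameterError(f"unknown role {role!r}")
        return [g for g in self.groups if g.role == role]

    def get(self, name: str) -> VariableGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(f"no group named {name!r}")

    @property
    def group_names(self) -> list[str]:
        return [g.name for g in self.groups]

    def validate_roles(self) -> None:
        """Require at least one group per role (needed for a full TMR run)."""
        for role in ROLES:
            if not self.by_role(role):
                raise ValidationError(f"dataset has no {role!r} group")


def align_dataset(groups: list[VariableGroup]) -> TMRDataset:
    """Restrict all groups to their common samples, in canonical (sorted) order.

    Samples with missing values are dropped per group (and logged) before the
    intersection is taken, since the downstream regression machinery requires
    complete cases.  Column order within each group is preserved.

    Raises
    ------
    ValidationError
        If two groups share a name or no groups are given.
    AlignmentError
        If the sample intersection is empty (names the disjoint groups).
    """
    if not groups:
        raise ValidationError("no groups to align")
    names = [g.name for g in groups]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate group names: {dupes}")

    cleaned = [g.dropna_samples() for g in groups]
    common = set(cleaned[0].samples)
    for g in cleaned[1:]:
        common &= set(g.samples)
    if not common:
        # name a disjoint pair to aid debugging
        for i, gi in enumerate(cleaned):
            for gj in cleaned[i + 1:]:
                if not set(gi.samples) & set(gj.samples):
                    raise AlignmentError(
                        f"groups {gi.name!r} and {gj.name!r} share no samples"
                    )
        raise AlignmentError("sample intersection across all groups is empty")

    index = sorted(common)
    for g in cleaned:
        n_dropped = g.n_samples - len(index)
        if n_dropped:
            logger.info("group %r: %d sample(s) outside the common index", g.name, n_dropped)
    aligned = [g.restrict(index) for g in cleaned]
    return TMRDataset(groups=aligned, sample_index=index)


@dataclass
class DoseResponseSeries:
    """One lung-function parameter measured across nebulized doses.

    ``parameter`` names the flexiVent quantity (H, G, Rn, Ers, Rrs); ``doses``
    are the nebulized methacholine concentrations in mg/mL, strictly
    increasing; ``responses`` the measured values at those doses.
    """

    doses: np.ndarray
    responses: np.ndarray
    parameter: str = ""

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.ndim != 1 or self.responses.ndim != 1:
            raise ValidationError("doses and responses must be 1-D")
        if len(self.doses) != len(self.responses):
            raise ValidationError("doses and responses must have equal length")
        if np.any(self.doses < 0) or not np.all(np.isfinite(self.doses)):
            raise ValidationError("doses must be finite and nonnegative")
        if np.any(np.diff(self.doses) <= 0):
            raise ValidationError("doses must be strictly increasing")


def derive_response_features(
    series: DoseResponseSeries, dose_scale: str = "linear"
) -> tuple[float, float]:
    """Reduce a dose-response series to (baseline, slope).

    The baseline is the response at the lowest nebulized dose (dose 0 when
    present).  The slope is the ordinary least-squares slope of response
    against dose.  With ``dose_scale="log"`` the fit uses the natural log of
    dose and points at dose 0 are excluded from the slope fit (but the
    baseline is still taken at the lowest dose).

    Raises
    ------
    InsufficientDataError
        Fewer than 2 usable dose points.
    ValidationError
        Non-finite responses.
    ParameterError
        Unknown ``dose_scale``.
    """
    if dose_scale not in ("linear", "log"):
        raise ParameterError(f"dose_scale must be 'linear' or 'log', got {dose_scale!r}")
    if not np.all(np.isfinite(series.responses)):
        raise ValidationError(f"series {series.parameter!r}: non-finite response")
    if len(series.doses) < 2:
        raise InsufficientDataError(
            f"series {series.parameter!r}: need at least 2 dose points"
        )
    baseline = float(series.responses[0])

    d, r = series.doses, series.responses
    if dose_scale == "log":
        keep = d > 0
        if keep.sum() < 2:
            raise InsufficientDataError(
                f"series {series.parameter!r}: need at least 2 positive doses for a log-dose slope"
            )
        d, r = np.log(d[keep]), r[keep]
    # closed-form OLS slope
    dc = d - d.mean()
    slope = float(dc @ (r - r.mean()) / (dc @ dc))
    return baseline, slope


def parse_series_columns(columns) -> dict[str, list[tuple[float, str]]]:
    """Group ``<parameter>@<dose>`` column names by parameter, sorted by dose."""
    by_param: dict[str, list[tuple[float, str]]] = {}
    for col in columns:
        if DOSE_SEPARATOR not in col:
            raise ValidationError(
                f"column {col!r} does not follow the '<parameter>@<dose>' convention"
            )
        param, dose_str = col.rsplit(DOSE_SEPARATOR, 1)
        try:
            dose = float(dose_str)
        except ValueError as exc:
            raise ValidationError(f"column {col!r}: dose {dose_str!r} is not numeric") from exc
        by_param.setdefault(param, []).append((dose, col))
    for param in by_param:
        by_param[param].sort(key=lambda t: t[0])
    return by_param


def derive_response_group(group: VariableGroup, dose_scale: str = "linear") -> VariableGroup:
    """Convert a dose-response series group into baseline/slope features.

    Input columns follow the ``<parameter>@<dose>`` convention; the output
    group carries ``<parameter>_baseline`` and ``<parameter>_slope`` columns
    with the same group name and role.
    """
    by_param = parse_series_columns(group.variables)
    out = {}
    for param, pairs in by_param.items():
        doses = np.array([d for d, _ in pairs])
        cols = [c for _, c in pairs]
        baselines, slopes = [], []
        for _, row in group.data[cols].iterrows():
            series = DoseResponseSeries(doses, row.to_numpy(dtype=float), parameter=param)
            b, s = derive_response_features(series, dose_scale=dose_scale)
            baselines.append(b)
            slopes.append(s)
        out[f"{param}_baseline"] = baselines
        out[f"{param}_slope"] = slopes
    frame = pd.DataFrame(out, index=group.data.index)
    meta = dict(group.meta)
    meta.pop("dose_response", None)
    meta["derived_from_dose_response"] = True
    meta["dose_scale"] = dose_scale
    return VariableGroup(name=group.name, role=group.role, data=frame, meta=meta)
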