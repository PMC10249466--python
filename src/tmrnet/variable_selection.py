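"""PCA-based variable selection with normality-driven transforms.

High-dimensional omics blocks are reduced before association scanning:

1. each variable is Shapiro-Wilk tested; when normality is rejected, square
   root and natural log transforms are tried and the one with the largest W
   statistic is kept (identity when neither applies or neither improves W);
2. PCA is run on the correlation matrix of the (transformed) variables;
3. principal components contributing more than ``variance_threshold`` (default
   1%) of the total variance are retained;
4. for each retained PC, in PC order, the not-yet-selected variable with the
   largest absolute Pearson correlation to the PC scores becomes its *proxy*.

The proxies — observed variables, not abstract component scores — are what
enter the downstream regressions, so results stay interpretable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import VariableGroup
from .exceptions import DegenerateDataError, InsufficientDataError, ParameterError

logger = logging.getLogger(__name__)

TRANSFORMS = ("identity", "sqrt", "log")


@dataclass
class TransformRecord:
    """Outcome of the per-variable normality check.

    W statistics for inapplicable transforms are ``None`` (sqrt requires a
    nonnegative minimum; log a positive one — zeros are offset by half the
    smallest positive value, recorded in ``log_offset``).
    """

    variable: str
    chosen: str
    w_raw: float
    p_raw: float
    w_sqrt: float | None = None
    w_log: float | None = None
    log_offset: float = 0.0


def _log_candidate(x: np.ndarray) -> tuple[np.ndarray, float] | None:
    mn = x.min()
    if mn > 0:
        return np.log(x), 0.0
    if mn < 0:
        return None
    positive = x[x > 0]
    if positive.size == 0:
        return None
    offset = positive.min() / 2.0
    return np.log(x + offset), offset


def choose_transform(
    values,
    variable: str = "x",
    normality_alpha: float = 0.05,
    always_compare: bool = False,
) -> TransformRecord:
    """Pick identity/sqrt/log for one variable by Shapiro-Wilk W.

    Transforms are only tried when raw normality is rejected at
    ``normality_alpha`` (set ``always_compare=True`` to always compare all
    applicable candidates).  "Better" means a larger W; ties keep the earlier
    entry in (identity, sqrt, log).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise InsufficientDataError(f"variable {variable!r}: need >= 3 finite values")
    if np.ptp(x) == 0:
        raise DegenerateDataError(f"variable {variable!r}: constant values")

    w_raw, p_raw = stats.shapiro(x)
    record = TransformRecord(variable=variable, chosen="identity",
                             w_raw=float(w_raw), p_raw=float(p_raw))
    if p_raw >= normality_alpha and not always_compare:
        return record

    candidates = {"identity": float(w_raw)}
    if x.min() >= 0:
        w_sqrt, _ = stats.shapiro(np.sqrt(x))
        record.w_sqrt = float(w_sqrt)
        candidates["sqrt"] = record.w_sqrt
    logged = _log_candidate(x)
    if logged is not None:
        lx, offset = logged
        w_log, _ = stats.shapiro(lx)
        record.w_log = float(w_log)
        record.log_offset = offset
        candidates["log"] = record.w_log

    record.chosen = max(TRANSFORMS, key=lambda t: (candidates.get(t, -math.inf), -TRANSFORMS.index(t)))
    return record


def apply_transform(values, record: TransformRecord) -> np.ndarray:
    """Apply a chosen transform to a vector."""
    x = np.asarray(values, dtype=float)
    if record.chosen == "identity":
        return x
    if record.chosen == "sqrt":
        return np.sqrt(x)
    if record.chosen == "log":
        return np.log(x + record.log_offset)
    raise ParameterError(f"unknown transform {record.chosen!r}")


def transform_group(
    group: VariableGroup,
    normality_alpha: float = 0.05,
    always_compare: bool = False,
) -> tuple[VariableGroup, list[TransformRecord]]:
    """Run :func:`choose_transform` column-wise and return the transformed group."""
    records = []
    data = {}
    for var in group.variables:
        rec = choose_transform(
            group.data[var].to_numpy(dtype=float),
            variable=var,
            normality_alpha=normality_alpha,
            always_compare=always_compare,
        )
        records.append(rec)
        data[var] = apply_transform(group.data[var].to_numpy(dtype=float), rec)
    frame = pd.DataFrame(data, index=group.data.index, columns=group.variables)
    meta = dict(group.meta)
    meta["transforms"] = {r.variable: r.chosen for r in records}
    return replace(group, data=frame, meta=meta), records


@dataclass
class PCSelection:
    """One retained principal component and its proxy variable."""

    pc_index: int                  # 1-based
    variance_fraction: float
    proxy_variable: str
    proxy_correlation: float       # signed Pearson r between proxy and PC scores


def pca_select(
    group: VariableGroup, variance_threshold: float = 0.01
) -> list[PCSelection]:
    """Retain PCs of the correlation matrix and pick one proxy variable each.

    Retention is strict: a PC is kept when its variance fraction exceeds
    ``variance_threshold``.  Proxies are assigned greedily in PC order among
    the not-yet-selected variables, by maximal ``|r|`` with the PC scores;
    exact ties break lexicographically by variable name.  When the greedy
    constraint changes the unconstrained argmax, the event is logged.
    """
    if not 0 <= variance_threshold < 1:
        raise ParameterError("variance_threshold must be in [0, 1)")
    x = group.values
    n, p = x.shape
    if n < 3:
        raise InsufficientDataError(f"group {group.name!r}: need >= 3 samples for PCA")
    if p < 2:
        raise InsufficientDataError(f"group {group.name!r}: need >= 2 variables for PCA")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [group.variables[j] for j in np.flatnonzero(sd == 0)]
        raise DegenerateDataError(f"group {group.name!r}: constant variable(s) {bad}")

    z = (x - x.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    fractions = np.maximum(eigvals, 0.0) / p  # trace of a correlation matrix is p
    scores = z @ eigvecs

    selections: list[PCSelection] = []
    taken: set[str] = set()
    for k in range(p):
        if fractions[k] <= variance_threshold:
            continue
        s = scores[:, k]
        if s.std(ddof=1) == 0:
            continue
        corrs = {}
        for j, var in enumerate(group.variables):
            r = np.corrcoef(z[:, j], s)[0, 1]
            corrs[var] = float(r)
        unconstrained = min(group.variables, key=lambda v: (-abs(corrs[v]), v))
        available = [v for v in group.variables if v not in taken]
        if not available:
            break
        # tie-break: larger |r| first, then lexicographic name
        proxy = min(available, key=lambda v: (-abs(corrs[v]), v))
        if proxy != unconstrained:
            logger.info(
                "group %r PC%d: proxy %r chosen under the distinctness constraint "
                "(unconstrained argmax was %r)", group.name, k + 1, proxy, unconstrained,
            )
        taken.add(proxy)
        selections.append(
            PCSelection(
                pc_index=k + 1,
                variance_fraction=float(fractions[k]),
                proxy_variable=proxy,
                proxy_correlation=corrs[proxy],
            )
        )
    return selections


def reduce_to_proxies(group: VariableGroup, selections: list[PCSelection]) -> VariableGroup:
    """Subset a group to the proxy variables, preserving column order."""
    chosen = {s.proxy_variable for s in selections}
    cols = [v for v in group.variables if v in chosen]
    meta = dict(group.meta)
    meta["proxy_selection"] = [
        (s.pc_index, s.proxy_variable, s.variance_fraction, s.proxy_correlation)
        for s in selections
    ]
    return replace(group, data=group.data[cols].copy(), meta=meta)


def select_variables(
    group: VariableGroup,
    variance_threshold: float = 0.01,
    normality_alpha: float = 0.05,
    always_compare: bool = False,
) -> tuple[list[TransformRecord], list[PCSelection], VariableGroup]:
    """Transform, PCA-select and reduce one group; returns all bookkeeping."""
    transformed, records = transform_group(
        group, normality_alpha=normality_alpha, always_compare=always_compare
    )
    selections = pca_select(transformed, variance_threshold=variance_threshold)
    reduced = reduce_to_proxies(transformed, selections)
    return records, selections, reduced


def selection_report(records: list[TransformRecord], selections: list[PCSelection]) -> pd.DataFrame:
    """Tabular summary of transforms and proxy selections for one group."""
    by_var = {r.variable: r for r in records}
    rows = []
    for s in selections:
        rec = by_var.get(s.proxy_variable)
        rows.append(
            {
                "pc_index": s.pc_index,
                "variance_fraction": s.variance_fraction,
                "proxy_variable": s.proxy_variable,
                "proxy_correlation": s.proxy_correlation,
                "transform": rec.chosen if rec else "identity",
            }
        )
    return pd.DataFrame(rows)
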