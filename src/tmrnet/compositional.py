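"""Compositional handling of 16S taxa tables.

Sequencing counts only carry relative information, so taxa tables are closed
to relative abundances, reduced to the dominant taxa with a pooled
``Remainder`` bucket, and mapped to unconstrained coordinates with the
additive log-ratio (ALR) transformation before any regression or distance
computation.  For a composition ``x`` with reference component ``ref`` and
pseudocount ``c``::

    alr_j(x) = ln((x_j + c) / (x_ref + c))        for every j != ref

The reference defaults to the ``Remainder`` bucket when present (always
positive after pooling) and otherwise to the taxon whose log abundance has
minimal variance; both the reference and the pseudocount are recorded in the
output group's metadata because the choice changes the coordinate system.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .data_model import VariableGroup
from .exceptions import DegenerateDataError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

REMAINDER = "Remainder"


def _check_nonnegative(group: VariableGroup) -> np.ndarray:
    x = group.values
    if not np.all(np.isfinite(x)):
        raise ValidationError(f"group {group.name!r}: non-finite abundances")
    if np.any(x < 0):
        raise ValidationError(f"group {group.name!r}: negative abundances")
    return x


def to_relative_abundance(group: VariableGroup) -> VariableGroup:
    """Close each sample row to sum 1.

    Raises :class:`DegenerateDataError` naming the sample for all-zero rows.
    Idempotent: applying it to an already-closed table changes nothing.
    """
    x = _check_nonnegative(group)
    row_sums = x.sum(axis=1)
    zero = row_sums == 0
    if np.any(zero):
        bad = [group.samples[i] for i in np.flatnonzero(zero)]
        raise DegenerateDataError(
            f"group {group.name!r}: all-zero sample row(s) {bad}"
        )
    data = pd.DataFrame(
        x / row_sums[:, None], index=group.data.index, columns=group.data.columns
    )
    meta = dict(group.meta)
    meta["units"] = "relative_abundance"
    return replace(group, data=data, meta=meta)


def select_top_taxa(group: VariableGroup, n: int = 10) -> VariableGroup:
    """Keep the ``n`` taxa with highest mean relative abundance; pool the rest.

    The pooled column is named ``Remainder`` and per-sample totals are
    preserved exactly.  Ties in mean abundance at the boundary are broken by
    lexicographic taxon name for determinism.  When ``n`` is at least the
    number of taxa, the table is returned unchanged apart from an appended
    all-zero ``Remainder`` column.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if group.meta.get("units") != "relative_abundance":
        raise ValidationError(
            f"group {group.name!r}: select_top_taxa expects relative abundances "
            "(apply to_relative_abundance first)"
        )
    if REMAINDER in group.variables:
        raise ValidationError(
            f"group {group.name!r}: a column named {REMAINDER!r} already exists"
        )
    means = group.data.mean(axis=0)
    ranked = sorted(group.variables, key=lambda v: (-means[v], v))
    kept = ranked[:n]
    pooled = ranked[n:]
    # preserve original column order among the kept taxa
    kept_in_order = [v for v in group.variables if v in set(kept)]
    data = group.data[kept_in_order].copy()
    if pooled:
        data[REMAINDER] = group.data[pooled].sum(axis=1)
    else:
        data[REMAINDER] = 0.0
    meta = dict(group.meta)
    meta["top_n_taxa"] = n
    meta["pooled_taxa"] = pooled
    return replace(group, data=data, meta=meta)


def _default_reference(group: VariableGroup, pseudocount: float) -> str:
    if REMAINDER in group.variables:
        return REMAINDER
    logged = np.log(group.values + pseudocount)
    variances = logged.var(axis=0, ddof=1)
    order = sorted(range(len(variances)), key=lambda j: (variances[j], group.variables[j]))
    return group.variables[order[0]]


def alr_transform(
    group: VariableGroup,
    reference: str | None = None,
    pseudocount: float = 1e-6,
) -> VariableGroup:
    """Additive log-ratio transform against a reference component.

    Natural logarithm throughout.  ``pseudocount`` must be positive unless
    every entry of the table is strictly positive, in which case 0 is allowed.
    The output has one column fewer than the input; ``meta["alr_reference"]``
    and ``meta["pseudocount"]`` record the coordinates used.
    """
    x = _check_nonnegative(group)
    if pseudocount < 0:
        raise ParameterError(f"pseudocount must be positive, got {pseudocount}")
    if pseudocount == 0 and np.any(x == 0):
        raise ParameterError("pseudocount 0 is only allowed when all entries are positive")
    if reference is None:
        reference = _default_reference(group, max(pseudocount, 1e-12))
        logger.info("group %r: ALR reference defaulted to %r", group.name, reference)
    if reference not in group.variables:
        raise ParameterError(
            f"group {group.name!r}: reference {reference!r} not among its variables"
        )
    ref = group.data[reference].to_numpy(dtype=float)
    others = [v for v in group.variables if v != reference]
    mat = group.data[others].to_numpy(dtype=float)
    out = np.log(mat + pseudocount) - np.log(ref + pseudocount)[:, None]
    if not np.all(np.isfinite(out)):
        raise ValidationError(
            f"group {group.name!r}: non-finite ALR values (zero reference without pseudocount?)"
        )
    data = pd.DataFrame(out, index=group.data.index, columns=others)
    meta = dict(group.meta)
    meta.update(
        {"units": "alr", "alr_reference": reference, "pseudocount": pseudocount,
         "compositional": False}
    )
    return replace(group, data=data, meta=meta)


def prepare_compositional(
    group: VariableGroup,
    top_n: int = 10,
    reference: str | None = None,
    pseudocount: float = 1e-6,
) -> VariableGroup:
    """Full 16S preprocessing: close, keep top taxa, ALR-transform."""
    rel = to_relative_abundance(group)
    top = select_top_taxa(rel, n=top_n)
    return alr_transform(top, reference=reference, pseudocount=pseudocount)
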