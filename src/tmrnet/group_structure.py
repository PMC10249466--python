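"""Inter-group structure: distance matrices, Mantel correlation, Ward dendrogram.

Each variable group induces a Euclidean inter-sample distance matrix (N x N,
computed on per-variable z-scored values by default, since groups mix units).
The similarity of two groups is the Pearson correlation of the strictly upper
triangles of their distance matrices — the Mantel statistic — and the
inter-group dissimilarity is ``1 - |cor|``.  Groups are then hierarchically
clustered with Ward's minimum-variance criterion via the Lance-Williams
recurrence and exported as a Newick dendrogram.

Two Ward variants are offered.  ``"ward.d"`` (default) applies the recurrence
directly to the 1-|cor| dissimilarities; ``"ward.d2"`` applies it to their
squares and reports square-root heights (the scipy/classic-distance form).
The variant used is recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .data_model import VariableGroup
from .exceptions import (
    AlignmentError,
    DegenerateDataError,
    ParameterError,
    ValidationError,
)

WARD_VARIANTS = ("ward.d", "ward.d2")


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative inter-sample distance matrix with labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if n < 2:
            raise ValidationError("distance matrix needs at least 2 samples")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValidationError("distance matrix diagonal must be exactly 0")
        if np.any(self.values < 0):
            raise ValidationError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def upper_triangle(self) -> np.ndarray:
        i, j = np.triu_indices(self.n, k=1)
        return self.values[i, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def euclidean_distances(group: VariableGroup, standardize: bool = True) -> DistanceMatrix:
    """Pairwise Euclidean distances between samples over one group's variables.

    ``standardize`` z-scores each variable first (default, because groups mix
    units such as ALR coordinates, relative amounts and expression ratios).
    """
    x = group.values
    if x.shape[0] < 2:
        raise ValidationError(f"group {group.name!r}: need >= 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValidationError(f"group {group.name!r}: non-finite values")
    if standardize:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [group.variables[j] for j in np.flatnonzero(sd == 0)]
            raise DegenerateDataError(
                f"group {group.name!r}: constant variable(s) {bad} cannot be standardized"
            )
        x = (x - x.mean(axis=0)) / sd
    d = squareform(pdist(x, metric="euclidean"))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=tuple(group.samples), values=d)


def mantel_correlation(a: DistanceMatrix, b: DistanceMatrix) -> float:
    """Pearson correlation of the strictly-upper-triangle entries (Mantel statistic)."""
    if a.labels != b.labels:
        if set(a.labels) != set(b.labels):
            raise AlignmentError("distance matrices have different sample sets")
        raise AlignmentError("distance matrices have the same samples in different order")
    if a.n < 3:
        raise ValidationError("Mantel correlation needs >= 3 samples")
    ua, ub = a.upper_triangle(), b.upper_triangle()
    if ua.std() == 0 or ub.std() == 0:
        raise DegenerateDataError("zero-variance distance triangle")
    return float(np.corrcoef(ua, ub)[0, 1])


def intergroup_dissimilarity(
    groups: list[VariableGroup], standardize: bool = True
) -> pd.DataFrame:
    """Matrix of 1 - |Mantel cor| between all group pairs."""
    if len(groups) < 2:
        raise ParameterError("need at least 2 groups")
    mats = [euclidean_distances(g, standardize=standardize) for g in groups]
    names = [g.name for g in groups]
    k = len(groups)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            cor = mantel_correlation(mats[i], mats[j])
            out[i, j] = out[j, i] = 1.0 - abs(cor)
    return pd.DataFrame(out, index=names, columns=names)


@dataclass
class GroupDendrogram:
    """Ward merge tree over variable groups.

    ``merges`` lists (members_a, members_b, height) in merge order, where the
    members are tuples of leaf names; heights are nondecreasing.
    """

    leaves: list[str]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]
    dissimilarities: pd.DataFrame
    variant: str = "ward.d"

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights.

        A child's branch length is its parent's merge height minus the
        child's own merge height (0 for leaves).
        """
        height_of: dict[tuple[str, ...], float] = {(leaf,): 0.0 for leaf in self.leaves}
        newick_of: dict[tuple[str, ...], str] = {(leaf,): leaf for leaf in self.leaves}
        node = None
        for a, b, h in self.merges:
            la = h - height_of[a]
            lb = h - height_of[b]
            node = tuple(sorted(a + b))
            newick_of[node] = f"({newick_of[a]}:{la:.10g},{newick_of[b]}:{lb:.10g})"
            height_of[node] = h
        return (newick_of[node] if node else self.leaves[0]) + ";"


def ward_linkage(
    d: np.ndarray, labels: list[str], variant: str = "ward.d"
) -> list[tuple[tuple[str, ...], tuple[str, ...], float]]:
    """Agglomerative clustering via the Lance-Williams Ward recurrence.

    ``variant="ward.d"`` runs the recurrence on the dissimilarities as given;
    ``"ward.d2"`` squares them first and reports square-root merge heights
    (equivalent to scipy's ``linkage(..., method="ward")`` on distances).
    Ties in the minimum inter-cluster dissimilarity break lexicographically
    by member names.
    """
    if variant not in WARD_VARIANTS:
        raise ParameterError(f"variant must be one of {WARD_VARIANTS}, got {variant!r}")
    d = np.asarray(d, dtype=float)
    k = len(labels)
    if d.shape != (k, k):
        raise ValidationError("dissimilarity matrix shape does not match labels")
    work = d ** 2 if variant == "ward.d2" else d.copy()

    members: dict[int, tuple[str, ...]] = {i: (labels[i],) for i in range(k)}
    sizes: dict[int, int] = {i: 1 for i in range(k)}
    dist: dict[frozenset, float] = {
        frozenset((i, j)): work[i, j] for i in range(k) for j in range(i + 1, k)
    }
    merges = []
    next_id = k
    while len(members) > 1:
        pair = min(
            dist,
            key=lambda q: (dist[q], tuple(sorted(members[i] for i in q))),
        )
        i, j = sorted(pair)
        h = dist[pair]
        a, b = sorted((members[i], members[j]))
        merges.append((a, b, float(np.sqrt(h)) if variant == "ward.d2" else float(h)))

        ni, nj = sizes[i], sizes[j]
        new_dists = {}
        for m in members:
            if m in (i, j):
                continue
            nm = sizes[m]
            dim = dist[frozenset((i, m))]
            djm = dist[frozenset((j, m))]
            dij = h
            new_dists[m] = ((ni + nm) * dim + (nj + nm) * djm - nm * dij) / (ni + nj + nm)
        for q in list(dist):
            if i in q or j in q:
                del dist[q]
        del members[i], members[j], sizes[i], sizes[j]
        members[next_id] = tuple(sorted(a + b))
        sizes[next_id] = ni + nj
        for m, v in new_dists.items():
            dist[frozenset((next_id, m))] = v
        next_id += 1
    return merges


def group_dendrogram(
    groups: list[VariableGroup],
    standardize: bool = True,
    variant: str = "ward.d",
) -> GroupDendrogram:
    """Ward dendrogram of variable groups from their 1-|Mantel cor| distances."""
    diss = intergroup_dissimilarity(groups, standardize=standardize)
    merges = ward_linkage(diss.to_numpy(), list(diss.index), variant=variant)
    return GroupDendrogram(
        leaves=list(diss.index), merges=merges, dissimilarities=diss, variant=variant
    )
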