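"""Classical MDS (principal coordinates) and PERMANOVA on distance matrices.

Classical multidimensional scaling embeds samples from a distance matrix by
eigen-decomposing the double-centered matrix ``-1/2 * J D^2 J``; axes are
scaled by the square roots of the (nonnegative) eigenvalues, so Euclidean
input distances are reproduced exactly.

PERMANOVA partitions the total sum of squares of the Gower-centered
inner-product matrix ``G`` by a sequence of covariates.  With hat matrix
``H_k`` of the design containing the intercept and the first ``k`` covariates,
the sequential (type-I) sum of squares of term ``k`` is
``tr(H_k G) - tr(H_{k-1} G)``; the pseudo-F compares it to the residual mean
square, and significance comes from unrestricted permutation of the sample
labels with the add-one estimator ``p = (1 + #{F* >= F}) / (1 + n_perm)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    CollinearityError,
    ParameterError,
)
from .group_structure import DistanceMatrix


@dataclass
class MDSResult:
    """Principal-coordinate embedding of a distance matrix."""

    labels: tuple[str, ...]
    coordinates: np.ndarray        # samples x k (k axes with positive eigenvalues)
    eigenvalues: np.ndarray        # all n eigenvalues, nonincreasing
    variance_explained: np.ndarray  # per returned axis, fraction of positive eigenvalue mass

    def to_frame(self) -> pd.DataFrame:
        cols = [f"MDS{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def classical_mds(d: DistanceMatrix, k: int = 2) -> MDSResult:
    """Top-``k`` principal coordinates of a distance matrix.

    Negative eigenvalues (possible for non-Euclidean input) are reported in
    ``eigenvalues`` but contribute no axes; if fewer than ``k`` positive
    eigenvalues exist, fewer axes are returned.
    """
    n = d.n
    if not 1 <= k < n:
        raise ParameterError(f"k must satisfy 1 <= k < n_samples ({n}), got {k}")
    g = _gower_center(d.values)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > max(1e-12 * abs(eigvals[0]), 0.0)
    use = np.flatnonzero(positive)[:k]
    coords = eigvecs[:, use] * np.sqrt(eigvals[use])
    pos_total = eigvals[positive].sum()
    var_exp = eigvals[use] / pos_total if pos_total > 0 else np.zeros(len(use))
    return MDSResult(
        labels=d.labels,
        coordinates=coords,
        eigenvalues=eigvals,
        variance_explained=var_exp,
    )


@dataclass
class PermanovaResult:
    """Sequential PERMANOVA decomposition with permutation p-values."""

    terms: list[str]
    df: np.ndarray
    sum_of_squares: np.ndarray
    pseudo_f: np.ndarray
    r_squared: np.ndarray
    p_values: np.ndarray
    residual_ss: float
    residual_df: int
    total_ss: float
    n_permutations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, term in enumerate(self.terms):
            rows.append(
                {
                    "term": term,
                    "df": int(self.df[i]),
                    "sum_of_squares": self.sum_of_squares[i],
                    "pseudo_F": self.pseudo_f[i],
                    "r_squared": self.r_squared[i],
                    "p_value": self.p_values[i],
                }
            )
        rows.append(
            {"term": "Residual", "df": self.residual_df,
             "sum_of_squares": self.residual_ss,
             "pseudo_F": np.nan, "r_squared": self.residual_ss / self.total_ss,
             "p_value": np.nan}
        )
        rows.append(
            {"term": "Total", "df": self.residual_df + int(self.df.sum()),
             "sum_of_squares": self.total_ss, "pseudo_F": np.nan,
             "r_squared": 1.0, "p_value": np.nan}
        )
        return pd.DataFrame(rows)


def _hat(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q @ q.T


def permanova(
    d: DistanceMatrix,
    covariates: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    sequential: bool = True,
) -> PermanovaResult:
    """Distance-based multivariate ANOVA with permutation inference.

    ``covariates`` must be a numeric DataFrame indexed by the same sample
    labels as ``d`` (any order; it is realigned).  Terms are the covariate
    columns, entered in the given order (type-I sums of squares by default;
    ``sequential=False`` gives marginal sums of squares against the full
    model).  Deterministic given ``(data, n_perm, seed)``.
    """
    if n_perm < 99:
        raise ParameterError(f"n_perm must be >= 99, got {n_perm}")
    if set(covariates.index.astype(str)) != set(d.labels):
        raise AlignmentError("covariate samples do not match the distance matrix labels")
    cov = covariates.copy()
    cov.index = cov.index.astype(str)
    cov = cov.loc[list(d.labels)]
    x = cov.to_numpy(dtype=float)
    n, k = x.shape
    terms = list(cov.columns)

    full = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise CollinearityError(
            f"covariates {terms} are collinear with each other or the intercept",
            columns=terms,
        )

    g = _gower_center(d.values)
    total_ss = float(np.trace(g))

    # per-term projection differences
    h_prev = _hat(np.ones((n, 1)))
    h_full = _hat(full)
    proj = []
    if sequential:
        h = h_prev
        for j in range(k):
            h_next = _hat(np.column_stack([np.ones(n), x[:, : j + 1]]))
            proj.append(h_next - h)
            h = h_next
    else:
        for j in range(k):
            reduced = np.column_stack([np.ones(n)] + [x[:, m] for m in range(k) if m != j])
            proj.append(h_full - _hat(reduced))
    m_res = np.eye(n) - h_full
    df_term = np.ones(k)
    df_res = n - 1 - k
    if df_res < 1:
        raise ParameterError("no residual degrees of freedom")

    def f_stats(gmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ss = np.array([float(np.sum(p * gmat)) for p in proj])
        ss_res = float(np.sum(m_res * gmat))
        f = (ss / df_term) / (ss_res / df_res)
        return ss, f

    ss_obs, f_obs = f_stats(g)
    ss_res = float(np.sum(m_res * g))

    rng = np.random.default_rng(seed)
    exceed = np.zeros(k)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        _, f_perm = f_stats(gp)
        exceed += f_perm >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    return PermanovaResult(
        terms=terms,
        df=df_term.astype(int),
        sum_of_squares=ss_obs,
        pseudo_f=f_obs,
        r_squared=ss_obs / total_ss,
        p_values=pvals,
        residual_ss=ss_res,
        residual_df=df_res,
        total_ss=total_ss,
        n_permutations=n_perm,
        seed=seed,
    )
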