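"""Covariate-adjusted linear association models of the TMR framework.

Three categories of ordinary-least-squares models link the variable groups:

1. treatment -> measured:   ``measured_i ~ treatments``
2. measured  -> measured:   ``measured_j ~ measured_i + treatments`` (both
   directions are fitted for every cross-group variable pair; a significant
   bidirectional pair is resolved to the stronger direction);
3. measured  -> response:   ``response ~ measured_i + treatments``

Every fitted coefficient yields a directed :class:`AssociationEdge` carrying
its estimate, Wald t statistic and two-sided p-value.  Edges significant at a
p cutoff (0.005 in the reference analyses) form a signed
:class:`AssociationNetwork`.

Treatment covariates (binary indicators plus continuous weight measures) are
entered jointly in every model.  When a covariate remains significant while a
measured predictor is in the model, its edge is emitted too, flagged as
*covariate-surfaced*.

The OLS core is a vectorized multi-response solver: a scan fits one design
matrix per measured predictor against all eligible response columns at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import TMRDataset, VariableGroup
from .exceptions import (
    CollinearityError,
    InsufficientDataError,
    ParameterError,
)

logger = logging.getLogger(__name__)

NodeId = tuple[str, str]  # (group name, variable name)


def t_pvalue(t: float, df: int) -> float:
    """Two-sided tail probability of |T| >= |t| under Student's t."""
    if df < 1:
        raise ParameterError(f"df must be >= 1, got {df}")
    if not np.isfinite(t):
        raise ParameterError(f"t must be finite, got {t}")
    return float(2.0 * stats.t.sf(abs(t), df))


def _check_rank(X: np.ndarray, labels: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # flag trailing pivots of a pivoted QR as the dependent columns
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        dependent = [labels[j] for j in piv[rank:]]
        raise CollinearityError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"dependent column(s): {dependent}", columns=dependent,
        )


def ols_multi(X: np.ndarray, Y: np.ndarray, labels: list[str] | None = None) -> dict:
    """Multi-response OLS of every column of ``Y`` on the design ``X``.

    ``X`` must already contain the intercept column.  Returns per-response
    arrays: ``coef``/``se``/``t``/``p`` of shape (p, q), ``r_squared`` (q,)
    and the common residual ``df``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    labels = labels if labels is not None else [f"x{j}" for j in range(p)]
    if n < p + 1:
        raise InsufficientDataError(f"n={n} too small for {p} design columns")
    _check_rank(X, labels)

    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ X.T @ Y
    resid = Y - X @ coef
    df = n - p
    ssr = (resid ** 2).sum(axis=0)
    sigma2 = ssr / df
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, coef / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(tss > 0, 1.0 - ssr / tss, 0.0)
    return {"coef": coef, "se": se, "t": tvals, "p": pvals,
            "r_squared": r2, "df_resid": df}


@dataclass
class FitSummary:
    """Per-predictor inference for one linear fit (intercept included)."""

    response: NodeId
    predictors: list[NodeId]
    coef: np.ndarray          # aligned with ["Intercept"] + predictors
    se: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    r_squared: float
    df_resid: int

    @property
    def terms(self) -> list[str]:
        return ["Intercept"] + [f"{g}::{v}" for g, v in self.predictors]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "t": self.t_values, "p": self.p_values},
            index=self.terms,
        )


def fit_ols(
    response,
    predictors,
    predictor_labels: list[NodeId] | None = None,
    response_label: NodeId = ("", "y"),
) -> FitSummary:
    """OLS with intercept of one response vector on a predictor matrix.

    Requires ``n >= n_predictors + 2`` so the residual df is at least 1.
    """
    y = np.asarray(response, dtype=float)
    Xp = np.asarray(predictors, dtype=float)
    if Xp.ndim == 1:
        Xp = Xp[:, None]
    n, k = Xp.shape
    if predictor_labels is None:
        predictor_labels = [("", f"x{j + 1}") for j in range(k)]
    if n < k + 2:
        raise InsufficientDataError(
            f"need at least {k + 2} samples for {k} predictors, got {n}"
        )
    X = np.column_stack([np.ones(n), Xp])
    labels = ["Intercept"] + [f"{g}::{v}" for g, v in predictor_labels]
    res = ols_multi(X, y, labels=labels)
    return FitSummary(
        response=response_label,
        predictors=list(predictor_labels),
        coef=res["coef"][:, 0],
        se=res["se"][:, 0],
        t_values=res["t"][:, 0],
        p_values=res["p"][:, 0],
        r_squared=float(res["r_squared"][0]),
        df_resid=res["df_resid"],
    )


def fit_joint_model(
    predictors: VariableGroup, responses: VariableGroup
) -> list[FitSummary]:
    """Multivariate-Y / multiple-X fit: every response on ALL predictor columns.

    This is the joint-group style used when a whole omics block (e.g. the top
    gut taxa in ALR coordinates) predicts each lung-function parameter.
    """
    labels = [(predictors.name, v) for v in predictors.variables]
    out = []
    for var in responses.variables:
        out.append(
            fit_ols(
                responses.data[var].to_numpy(dtype=float),
                predictors.values,
                predictor_labels=labels,
                response_label=(responses.name, var),
            )
        )
    return out


@dataclass(frozen=True)
class AssociationEdge:
    """A directed predictor -> response association from one TMR model."""

    predictor: NodeId
    response: NodeId
    beta: float
    se: float
    t: float
    p_value: float
    category: int
    covariates_controlled: tuple[str, ...] = ()
    covariate_surfaced: bool = False

    @property
    def sign(self) -> str:
        return "positive" if self.beta >= 0 else "negative"


def _treatment_matrix(dataset: TMRDataset) -> tuple[np.ndarray, list[NodeId]]:
    blocks, labels = [], []
    for g in dataset.by_role("treatment"):
        blocks.append(g.values)
        labels.extend((g.name, v) for v in g.variables)
    if not blocks:
        raise ParameterError("dataset has no treatment group")
    return np.hstack(blocks), labels


def _edges_from_fit(res, col_labels, row_labels, category_of, covariates, alpha_report):
    """Translate an ols_multi result into AssociationEdge objects.

    ``row_labels`` are design columns (excluding intercept) and
    ``col_labels`` response columns.  The first design row after the
    intercept that is NOT a covariate (if any) is the primary predictor and
    is always emitted; covariate rows are emitted only at p < alpha_report,
    flagged as covariate-surfaced (unless the model is category 1, where
    covariates ARE the primary predictors).
    """
    edges = []
    cov_set = set(covariates)
    controlled = tuple(f"{g}::{v}" for g, v in covariates)
    for ci, resp in enumerate(col_labels):
        category = category_of(resp)
        for ri, pred in enumerate(row_labels):
            i = ri + 1  # skip intercept
            is_cov = pred in cov_set
            primary = not is_cov or category == 1
            p = float(res["p"][i, ci])
            if not primary and p >= alpha_report:
                continue
            edges.append(
                AssociationEdge(
                    predictor=pred,
                    response=resp,
                    beta=float(res["coef"][i, ci]),
                    se=float(res["se"][i, ci]),
                    t=float(res["t"][i, ci]),
                    p_value=p,
                    category=category,
                    covariates_controlled=controlled if category != 1 else (),
                    covariate_surfaced=not primary,
                )
            )
    return edges


def tmr_scan(
    dataset: TMRDataset,
    alpha_report: float = 0.05,
    include_covariate_edges: bool = True,
) -> list[AssociationEdge]:
    """Fit all three TMR model categories and emit association edges.

    Category-1 edges (one per treatment covariate and measured variable) and
    the primary measured-predictor edges of categories 2 and 3 are always
    emitted, whatever their p-value; covariate-surfaced edges of categories
    2-3 are emitted only below ``alpha_report`` (or never, when
    ``include_covariate_edges`` is False).  Filtering at the network cutoff
    happens later in :func:`build_network`.
    """
    dataset.validate_roles()
    n = len(dataset.sample_index)
    T, cov_labels = _treatment_matrix(dataset)
    _check_rank(np.column_stack([np.ones(n), T]),
                ["Intercept"] + [f"{g}::{v}" for g, v in cov_labels])

    measured = dataset.by_role("measured")
    responses = dataset.by_role("response")
    edges: list[AssociationEdge] = []

    # category 1: measured_i ~ treatments
    X1 = np.column_stack([np.ones(n), T])
    for g in measured:
        res = ols_multi(X1, g.values)
        col_labels = [(g.name, v) for v in g.variables]
        edges.extend(
            _edges_from_fit(res, col_labels, cov_labels, lambda _: 1,
                            cov_labels, alpha_report)
        )

    # categories 2 and 3 share designs: one per measured predictor variable
    resp_cols = []
    resp_labels: list[NodeId] = []
    for g in responses:
        resp_cols.append(g.values)
        resp_labels.extend((g.name, v) for v in g.variables)
    resp_mat = np.hstack(resp_cols) if resp_cols else None
    resp_set = set(resp_labels)

    if not include_covariate_edges:
        alpha_report = -1.0  # suppress covariate-surfaced edges entirely

    for gi in measured:
        others = [g for g in measured if g.name != gi.name]
        other_mat = np.hstack([g.values for g in others]) if others else None
        other_labels = [(g.name, v) for g in others for v in g.variables]
        for j, u in enumerate(gi.variables):
            cols = []
            col_labels: list[NodeId] = []
            if other_mat is not None:
                cols.append(other_mat)
                col_labels.extend(other_labels)
            if resp_mat is not None:
                cols.append(resp_mat)
                col_labels.extend(resp_labels)
            if not cols:
                continue
            Y = np.hstack(cols)
            X = np.column_stack([np.ones(n), gi.values[:, j], T])
            res = ols_multi(X, Y)
            row_labels = [(gi.name, u)] + cov_labels
            edges.extend(
                _edges_from_fit(
                    res, col_labels, row_labels,
                    lambda r: 3 if r in resp_set else 2,
                    cov_labels, alpha_report,
                )
            )
    return edges


def scan_measured_pair(
    dataset: TMRDataset, group_i: str, group_j: str
) -> list[AssociationEdge]:
    """Category-2 edges for one ordered pair of measured groups.

    Raises :class:`ParameterError` when the same group is named twice —
    within-group pairs are outside the framework by design.
    """
    if group_i == group_j:
        raise ParameterError(
            f"category-2 models require two distinct measured groups, got {group_i!r} twice"
        )
    gi, gj = dataset.get(group_i), dataset.get(group_j)
    for g in (gi, gj):
        if g.role != "measured":
            raise ParameterError(f"group {g.name!r} has role {g.role!r}, expected 'measured'")
    n = len(dataset.sample_index)
    T, cov_labels = _treatment_matrix(dataset)
    edges = []
    col_labels = [(gj.name, v) for v in gj.variables]
    for j, u in enumerate(gi.variables):
        X = np.column_stack([np.ones(n), gi.values[:, j], T])
        res = ols_multi(X, gj.values)
        row_labels = [(gi.name, u)] + cov_labels
        edges.extend(
            _edges_from_fit(res, col_labels, row_labels, lambda _: 2,
                            cov_labels, -1.0)
        )
    return edges


def resolve_bidirectional(
    edges: list[AssociationEdge], alpha: float = 0.005
) -> list[AssociationEdge]:
    """Keep the stronger direction of significant bidirectional cat-2 pairs.

    For each unordered variable pair whose BOTH directions are significant at
    ``alpha``, only the direction with the smaller p-value survives; exact
    ties go to the larger |t|, then to the lexicographically smaller
    (predictor, response) labelling.  Every removal is logged.  Edges of other
    categories, covariate-surfaced edges, and one-directional pairs pass
    through untouched.
    """
    by_pair: dict[frozenset, list[AssociationEdge]] = {}
    for e in edges:
        if e.category == 2 and not e.covariate_surfaced:
            by_pair.setdefault(frozenset((e.predictor, e.response)), []).append(e)

    drop: set[int] = set()
    for pair_edges in by_pair.values():
        significant = [e for e in pair_edges if e.p_value < alpha]
        directions = {(e.predictor, e.response) for e in significant}
        if len(directions) < 2:
            continue
        ranked = sorted(
            significant,
            key=lambda e: (e.p_value, -abs(e.t), (e.predictor, e.response)),
        )
        winner = (ranked[0].predictor, ranked[0].response)
        for e in pair_edges:
            if (e.predictor, e.response) != winner:
                drop.add(id(e))
                logger.info(
                    "bidirectional pair resolved: dropping %s -> %s (p=%.3g) in favour of %s -> %s (p=%.3g)",
                    e.predictor, e.response, e.p_value, *winner, ranked[0].p_value,
                )
    return [e for e in edges if id(e) not in drop]


@dataclass
class AssociationNetwork:
    """Signed association network at a p-value cutoff."""

    edges: list[AssociationEdge]
    alpha: float
    node_groups: dict[NodeId, str] = field(default_factory=dict)

    @property
    def nodes(self) -> list[NodeId]:
        return sorted(self.node_groups)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph(alpha=self.alpha)
        for (grp, var) in self.nodes:
            g.add_node(f"{grp}::{var}", group=grp, variable=var)
        for e in self.edges:
            g.add_edge(
                f"{e.predictor[0]}::{e.predictor[1]}",
                f"{e.response[0]}::{e.response[1]}",
                beta=e.beta,
                p=e.p_value,
                sign=e.sign,
                category=e.category,
            )
        return g

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


def build_network(edges: list[AssociationEdge], alpha: float) -> AssociationNetwork:
    """Retain edges with ``p < alpha`` (strict) as a signed network."""
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    kept = [e for e in edges if np.isfinite(e.p_value) and e.p_value < alpha]
    node_groups = {}
    for e in kept:
        node_groups[e.predictor] = e.predictor[0]
        node_groups[e.response] = e.response[0]
    return AssociationNetwork(edges=kept, alpha=alpha, node_groups=node_groups)


def edges_to_frame(edges: list[AssociationEdge]) -> pd.DataFrame:
    """Full edge table (one row per emitted association)."""
    rows = [
        {
            "predictor_group": e.predictor[0],
            "predictor": e.predictor[1],
            "response_group": e.response[0],
            "response": e.response[1],
            "beta": e.beta,
            "se": e.se,
            "t": e.t,
            "p": e.p_value,
            "category": e.category,
            "sign": e.sign,
            "covariate_surfaced": e.covariate_surfaced,
        }
        for e in edges
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "predictor_group", "predictor", "response_group", "response",
            "beta", "se", "t", "p", "category", "sign", "covariate_surfaced",
        ],
    )


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (optional FDR column for edge tables)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
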