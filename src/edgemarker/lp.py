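"""Linear-programming biomarker selection by ellipsoid separation.

Each class k is modelled as an ellipsoid around its centroid: with feature
weights ``w`` (edges first, then nodes) and per-sample deviations
``d_jik`` -- ``B_i (a_ji - a_ik)^2`` for an edge feature, ``(x_ji - x_ik)^2``
for a node feature -- the weighted deviation of an in-class sample must fall
inside an inner radius ``Z1_k`` and that of an out-of-class sample outside
an outer radius ``Z2_k``, each up to a non-negative slack ``eta_jk``:

    minimise   sum_edges w_i + lambda * sum_nodes w_i
             + alpha * sum_k (Z1_k - Z2_k) + C * sum_{j,k} eta_jk
    such that  sum_i w_i d_jik <= Z1_k + eta_jk   for j in class k
               sum_i w_i d_jik >= Z2_k - eta_jk   for j not in class k
               0 <= Z1_k <= Z2_k,  0 <= w_i <= 1,  eta_jk >= 0.

Minimising feature weights keeps the biomarker set small; the ``alpha`` term
widens the gap between inner and outer radii; the penalty ``C`` charges
radius violations (classification errors). The all-zero point is always
feasible with objective 0, so a sufficiently small ``alpha`` (or large
``C``) collapses the model to the trivial no-biomarker solution. Features
with optimal weight above a tolerance are reported as biomarkers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import linprog

from .features import ClassSpec, FeatureSystem
from .io import ValidationError

__all__ = [
    "ModelParams",
    "LPInstance",
    "LPSolution",
    "EdgeBiomarker",
    "NodeBiomarker",
    "BiomarkerSet",
    "GridCell",
    "GridSearchError",
    "build_lp",
    "solve_lp",
    "extract_biomarkers",
    "grid_search",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_C_GRID",
]

DEFAULT_ALPHA_GRID = (0.02, 0.1, 0.5, 1.0)
DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)


@dataclass
class ModelParams:
    """Trade-off parameters of the selection LP.

    lambda_ : relative cost of node weights versus edge weights (1 treats
        single genes and interactions as equally expensive biomarkers).
    alpha : reward per unit of inner/outer radius gap.
    penalty_C : cost per unit of slack (classification error). The class
        count is a separate quantity (``n_classes``); the shared symbol in
        the field's notation is split here.
    coexpression_cutoff : cutoff k applied to B before edge features enter.
    weight_tol : minimum optimal weight for a feature to count as selected.
    """

    lambda_: float = 1.0
    alpha: float = 0.1
    penalty_C: float = 100.0
    coexpression_cutoff: float = 0.5
    weight_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.lambda_ < 0 or self.alpha < 0 or self.penalty_C < 0:
            raise ValidationError("lambda_, alpha and penalty_C must be >= 0")


@dataclass
class LPInstance:
    """Assembled LP in inequality form (A_ub x <= b_ub, lb <= x <= ub).

    Variable layout: ``[w (p+n), Z1 (K), Z2 (K), eta (m*K, sample-major)]``.
    Rows: one per (sample, class) pair -- type "in" for j in class k, "out"
    otherwise -- followed by K radius-ordering rows ``Z1_k - Z2_k <= 0``.
    """

    c: np.ndarray
    A_ub: np.ndarray
    b_ub: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    n_edge_features: int
    n_node_features: int
    n_samples: int
    n_classes: int
    deviations: np.ndarray  # (m, p+n, K), all >= 0
    in_class: np.ndarray  # (m, K) boolean
    feature_names: list[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.n_edge_features + self.n_node_features

    @property
    def n_variables(self) -> int:
        return self.c.size

    # variable-block slices
    @property
    def sl_w(self) -> slice:
        return slice(0, self.n_features)

    @property
    def sl_z1(self) -> slice:
        return slice(self.n_features, self.n_features + self.n_classes)

    @property
    def sl_z2(self) -> slice:
        return slice(self.n_features + self.n_classes,
                     self.n_features + 2 * self.n_classes)

    @property
    def sl_eta(self) -> slice:
        return slice(self.n_features + 2 * self.n_classes, self.n_variables)

    @classmethod
    def from_deviations(
        cls,
        deviations: np.ndarray,
        in_class: np.ndarray,
        params: ModelParams,
        n_edge_features: int,
        feature_names: Sequence[str] | None = None,
    ) -> "LPInstance":
        """Build the LP from precomputed deviation constants.

        ``deviations[j, i, k]`` is feature i's squared (B-weighted) deviation
        of sample j from class k's centroid; ``in_class[j, k]`` marks class
        membership (each sample belongs to exactly one class).
        """
        D = np.asarray(deviations, dtype=float)
        in_class = np.asarray(in_class, dtype=bool)
        m, q, K = D.shape
        if in_class.shape != (m, K):
            raise ValidationError("in_class shape does not match deviations")
        if not (in_class.sum(axis=1) == 1).all():
            raise ValidationError("each sample must belong to exactly one class")
        if K < 2:
            raise ValidationError("at least two classes are required")
        if q < 1:
            raise ValidationError("empty feature system")
        p = int(n_edge_features)
        n = q - p

        n_vars = q + 2 * K + m * K
        c = np.zeros(n_vars)
        c[:p] = 1.0
        c[p:q] = params.lambda_
        c[q:q + K] = params.alpha  # Z1
        c[q + K:q + 2 * K] = -params.alpha  # Z2
        c[q + 2 * K:] = params.penalty_C  # eta

        def eta_col(j: int, k: int) -> int:
            return q + 2 * K + j * K + k

        rows = m * K + K
        A = np.zeros((rows, n_vars))
        b = np.zeros(rows)
        r = 0
        for j in range(m):
            for k in range(K):
                if in_class[j, k]:
                    # sum_i w_i d_jik - Z1_k - eta_jk <= 0
                    A[r, :q] = D[j, :, k]
                    A[r, q + k] = -1.0
                    A[r, eta_col(j, k)] = -1.0
                else:
                    # sum_i w_i d_jik >= Z2_k - eta_jk
                    A[r, :q] = -D[j, :, k]
                    A[r, q + K + k] = 1.0
                    A[r, eta_col(j, k)] = -1.0
                r += 1
        for k in range(K):  # Z1_k <= Z2_k
            A[r, q + k] = 1.0
            A[r, q + K + k] = -1.0
            r += 1

        lb = np.zeros(n_vars)
        ub = np.full(n_vars, np.inf)
        ub[:q] = 1.0
        return cls(
            c=c, A_ub=A, b_ub=b, lb=lb, ub=ub,
            n_edge_features=p, n_node_features=n,
            n_samples=m, n_classes=K,
            deviations=D, in_class=in_class,
            feature_names=list(feature_names or []),
        )


@dataclass
class LPSolution:
    status: str  # optimal | infeasible | unbounded | failed
    objective: float
    w: np.ndarray
    Z1: np.ndarray
    Z2: np.ndarray
    eta: np.ndarray
    message: str = ""

    @property
    def total_slack(self) -> float:
        return float(self.eta.sum())


def build_lp(
    features: FeatureSystem, classes: ClassSpec, params: ModelParams
) -> LPInstance:
    """Assemble the selection LP from a feature system and class centroids.

    Edge deviations are ``B_i (a_ji - a_ik)^2`` with the thresholded
    co-expression weight B_i; node deviations are ``(x_ji - x_ik)^2``.
    """
    if features.n_edges + features.n_nodes == 0:
        raise ValidationError("empty feature system")
    K = len(classes.classes)
    m = features.n_samples
    edge_cent = classes.edge_centroids[:, features.edge_src_idx]  # (K, p)
    node_cent = classes.node_centroids[:, features.node_src_idx]  # (K, n)
    # (m, p, K) and (m, n, K)
    edge_dev = (
        features.edge_affinity[:, :, None] - edge_cent.T[None, :, :]
    ) ** 2 * features.edge_coexpression[None, :, None]
    node_dev = (features.node_expression[:, :, None] - node_cent.T[None, :, :]) ** 2
    D = np.concatenate([edge_dev, node_dev], axis=1)
    in_class = np.zeros((m, K), dtype=bool)
    for k, cls_label in enumerate(classes.classes):
        in_class[classes.member_sets[cls_label], k] = True
    return LPInstance.from_deviations(
        D, in_class, params, features.n_edges, features.feature_names()
    )


_STATUS = {0: "optimal", 1: "failed", 2: "infeasible", 3: "unbounded", 4: "failed"}


def solve_lp(lp: LPInstance, feasibility_tol: float = 1e-8) -> LPSolution:
    """Solve the LP with HiGHS; deterministic for fixed inputs.

    On success the primal feasibility residual is verified against
    ``feasibility_tol`` (scaled by the constraint magnitude); a violation
    downgrades the status to ``failed`` rather than returning an unreliable
    point.
    """
    res = linprog(
        lp.c,
        A_ub=lp.A_ub,
        b_ub=lp.b_ub,
        bounds=list(zip(lp.lb, lp.ub)),
        method="highs",
    )
    status = _STATUS.get(res.status, "failed")
    if status != "optimal" or res.x is None:
        zeros_q = np.zeros(lp.n_features)
        zeros_k = np.zeros(lp.n_classes)
        return LPSolution(
            status=status,
            objective=float("nan"),
            w=zeros_q, Z1=zeros_k, Z2=zeros_k,
            eta=np.zeros((lp.n_samples, lp.n_classes)),
            message=str(res.message),
        )
    x = np.asarray(res.x)
    scale = max(1.0, float(np.abs(lp.A_ub @ x).max(initial=0.0)))
    residual = float((lp.A_ub @ x - lp.b_ub).max(initial=0.0))
    finite_ub = np.isfinite(lp.ub)
    bound_violation = float(
        max(
            (lp.lb - x).max(initial=0.0),
            (x - lp.ub)[finite_ub].max(initial=0.0),
        )
    )
    if residual > feasibility_tol * scale or bound_violation > feasibility_tol * scale:
        return LPSolution(
            status="failed",
            objective=float(res.fun),
            w=x[lp.sl_w], Z1=x[lp.sl_z1], Z2=x[lp.sl_z2],
            eta=x[lp.sl_eta].reshape(lp.n_samples, lp.n_classes),
            message=f"feasibility residual {residual:.3e} exceeds tolerance",
        )
    return LPSolution(
        status="optimal",
        objective=float(res.fun),
        w=x[lp.sl_w],
        Z1=x[lp.sl_z1],
        Z2=x[lp.sl_z2],
        eta=x[lp.sl_eta].reshape(lp.n_samples, lp.n_classes),
        message=str(res.message),
    )


@dataclass
class EdgeBiomarker:
    genes: tuple[str, str]
    weight: float
    coexpression: float


@dataclass
class NodeBiomarker:
    gene: str
    weight: float


@dataclass
class BiomarkerSet:
    """Selected edge and node biomarkers with their LP weights."""

    edge_biomarkers: list[EdgeBiomarker]
    node_biomarkers: list[NodeBiomarker]
    trivial: bool
    objective: float
    params: ModelParams

    @property
    def n_selected(self) -> int:
        return len(self.edge_biomarkers) + len(self.node_biomarkers)

    def selected_genes(self) -> set[str]:
        genes = {g for e in self.edge_biomarkers for g in e.genes}
        genes |= {nb.gene for nb in self.node_biomarkers}
        return genes

    def to_table(self) -> list[dict]:
        rows = []
        for e in self.edge_biomarkers:
            rows.append(
                {
                    "feature_id": f"{e.genes[0]}--{e.genes[1]}",
                    "type": "edge",
                    "gene_u": e.genes[0],
                    "gene_v": e.genes[1],
                    "weight": e.weight,
                    "B": e.coexpression,
                }
            )
        for nb in self.node_biomarkers:
            rows.append(
                {
                    "feature_id": nb.gene,
                    "type": "node",
                    "gene_u": nb.gene,
                    "gene_v": "NA",
                    "weight": nb.weight,
                    "B": "NA",
                }
            )
        return rows


def extract_biomarkers(
    sol: LPSolution, features: FeatureSystem, params: ModelParams
) -> BiomarkerSet:
    """Report features with optimal weight >= ``params.weight_tol``.

    Sorted by descending weight, ties broken by feature index. An all-zero
    weight vector yields an empty set flagged as the trivial solution.
    """
    if sol.status != "optimal":
        raise ValidationError(f"cannot extract biomarkers from status {sol.status!r}")
    p = features.n_edges
    idx = np.flatnonzero(sol.w >= params.weight_tol)
    order = sorted(idx, key=lambda i: (-sol.w[i], i))
    edges = [
        EdgeBiomarker(
            genes=features.edge_pairs[i],
            weight=float(sol.w[i]),
            coexpression=float(features.edge_coexpression[i]),
        )
        for i in order
        if i < p
    ]
    nodes = [
        NodeBiomarker(gene=features.node_genes[i - p], weight=float(sol.w[i]))
        for i in order
        if i >= p
    ]
    return BiomarkerSet(
        edge_biomarkers=edges,
        node_biomarkers=nodes,
        trivial=len(order) == 0,
        objective=sol.objective,
        params=params,
    )


class GridSearchError(RuntimeError):
    pass


@dataclass
class GridCell:
    alpha: float
    penalty_C: float
    trivial: bool
    n_biomarkers: int
    objective: float
    total_slack: float
    status: str
    cv_auc: float | None = None


def grid_search(
    features: FeatureSystem,
    classes: ClassSpec,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    selection_rule: str = "max_C",
    cv_scorer: Callable[[BiomarkerSet], float] | None = None,
    base_params: ModelParams | None = None,
) -> tuple[ModelParams, list[GridCell]]:
    """Solve the LP over an (alpha, C) grid and pick a parameter pair.

    ``selection_rule="max_C"`` keeps non-trivial cells and prefers the
    largest slack penalty C, then the smallest alpha (a non-trivial solution
    with few classification errors and few biomarkers).
    ``selection_rule="cv_auc"`` prefers the highest ``cv_scorer`` value with
    the same tie-break.
    """
    if not alpha_grid or not C_grid:
        raise ValidationError("alpha and C grids must be non-empty")
    if selection_rule not in ("max_C", "cv_auc"):
        raise ValidationError(f"unknown selection rule {selection_rule!r}")
    if selection_rule == "cv_auc" and cv_scorer is None:
        raise ValidationError("cv_auc rule requires a cv_scorer")
    base = base_params or ModelParams()
    cells: list[GridCell] = []
    for alpha in alpha_grid:
        for C in C_grid:
            params = replace(base, alpha=float(alpha), penalty_C=float(C))
            sol = solve_lp(build_lp(features, classes, params))
            if sol.status != "optimal":
                cells.append(
                    GridCell(alpha, C, True, 0, float("nan"), float("nan"),
                             sol.status)
                )
                continue
            bset = extract_biomarkers(sol, features, params)
            auc = None
            if cv_scorer is not None and not bset.trivial:
                auc = float(cv_scorer(bset))
            cells.append(
                GridCell(
                    alpha=float(alpha),
                    penalty_C=float(C),
                    trivial=bset.trivial,
                    n_biomarkers=bset.n_selected,
                    objective=sol.objective,
                    total_slack=sol.total_slack,
                    status=sol.status,
                    cv_auc=auc,
                )
            )
    eligible = [c for c in cells if not c.trivial and c.status == "optimal"]
    if not eligible:
        raise GridSearchError(
            "every grid cell yielded the trivial solution; extend the grid "
            "towards larger alpha or smaller C"
        )
    if selection_rule == "max_C":
        best = max(eligible, key=lambda c: (c.penalty_C, -c.alpha))
    else:
        best = max(eligible, key=lambda c: (c.cv_auc, c.penalty_C, -c.alpha))
    return replace(base, alpha=best.alpha, penalty_C=best.penalty_C), cells
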