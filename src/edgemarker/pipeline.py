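"""End-to-end biomarker selection: filters -> features -> LP -> extraction."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .features import (
    ClassSpec,
    FeatureSystem,
    InteractionNetwork,
    MassActionParams,
    anchor_edge_filter,
    assemble_features,
    class_centroids,
    mass_action_affinity,
    spearman_coexpression,
    threshold_coexpression,
)
from .io import ExpressionMatrix
from .lp import (
    BiomarkerSet,
    GridCell,
    LPSolution,
    ModelParams,
    build_lp,
    extract_biomarkers,
    grid_search,
    solve_lp,
)

__all__ = ["SelectionResult", "build_feature_system", "select_biomarkers",
           "grid_select"]


@dataclass
class SelectionResult:
    biomarkers: BiomarkerSet
    solution: LPSolution
    features: FeatureSystem
    classes: ClassSpec
    params: ModelParams


def build_feature_system(
    expr: ExpressionMatrix,
    net: InteractionNetwork,
    params: ModelParams,
    anchors: Iterable[str] | None = None,
    node_genes: Sequence[str] | None = None,
    coexpression_scope: str = "per_class_max",
    formula_mode: str = "standard",
    absolute_coexpression: bool = False,
    mass_action: MassActionParams | None = None,
) -> tuple[FeatureSystem, ClassSpec]:
    """Construct the joint edge+node feature system and class centroids.

    The default co-expression scope is ``"per_class_max"``: an edge's B is
    computed within each class and the maximum kept, so pairs that are
    strongly co-expressed in one context survive the cutoff even when the
    pooled correlation cancels (the signature of differential
    co-expression). Pass ``coexpression_scope="pooled"`` for the all-sample
    coefficient.
    """
    if anchors is not None:
        net = anchor_edge_filter(net, anchors)
    # restrict the network to genes present after upstream filtering
    present = set(expr.gene_ids)
    net = InteractionNetwork([e for e in net.edges
                              if e[0] in present and e[1] in present])
    weights = spearman_coexpression(
        expr, net, formula_mode=formula_mode, scope=coexpression_scope
    )
    weights = threshold_coexpression(
        weights, params.coexpression_cutoff, absolute=absolute_coexpression
    )
    aff = mass_action_affinity(expr, net, mass_action)
    features = assemble_features(aff, weights, expr, node_genes)
    classes = class_centroids(aff, expr)
    return features, classes


def select_biomarkers(
    expr: ExpressionMatrix,
    net: InteractionNetwork,
    params: ModelParams | None = None,
    **feature_kwargs,
) -> SelectionResult:
    """Run the full selection: co-expression cutoff, affinities, LP, report."""
    params = params or ModelParams()
    features, classes = build_feature_system(expr, net, params, **feature_kwargs)
    lp = build_lp(features, classes, params)
    sol = solve_lp(lp)
    biomarkers = extract_biomarkers(sol, features, params)
    return SelectionResult(biomarkers, sol, features, classes, params)


def grid_select(
    expr: ExpressionMatrix,
    net: InteractionNetwork,
    alpha_grid=None,
    C_grid=None,
    selection_rule: str = "max_C",
    cv_scorer=None,
    base_params: ModelParams | None = None,
    **feature_kwargs,
) -> tuple[SelectionResult, list[GridCell]]:
    """Grid-search (alpha, C), then re-solve at the chosen pair."""
    from .lp import DEFAULT_ALPHA_GRID, DEFAULT_C_GRID

    base = base_params or ModelParams()
    features, classes = build_feature_system(expr, net, base, **feature_kwargs)
    best_params, cells = grid_search(
        features,
        classes,
        alpha_grid=alpha_grid or DEFAULT_ALPHA_GRID,
        C_grid=C_grid or DEFAULT_C_GRID,
        selection_rule=selection_rule,
        cv_scorer=cv_scorer,
        base_params=base,
    )
    lp = build_lp(features, classes, best_params)
    sol = solve_lp(lp)
    biomarkers = extract_biomarkers(sol, features, best_params)
    return SelectionResult(biomarkers, sol, features, classes, best_params), cells
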