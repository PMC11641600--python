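"""Edge and node feature construction for network-based biomarker selection.

Each protein-protein interaction (u, v) gets a per-sample *affinity*
``a_ji = alpha * x_ju**a * x_jv**b`` -- the law-of-mass-action proxy for the
concentration of the u:v complex, with reaction constant and stoichiometric
coefficients defaulting to 1 so that the affinity is simply the product of
the two partners' expression levels. Edges additionally carry a Spearman
co-expression weight ``B_uv`` that is zeroed below a cutoff ``k`` to impose
context specificity; the surviving ``B`` multiplies the edge's squared
deviation terms in the downstream linear program. Node features are plain
expression columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .io import ExpressionMatrix, ValidationError

__all__ = [
    "InteractionNetwork",
    "MassActionParams",
    "AffinityMatrix",
    "CoexpressionWeights",
    "ClassSpec",
    "FeatureSystem",
    "mass_action_affinity",
    "class_centroids",
    "spearman_coexpression",
    "threshold_coexpression",
    "anchor_edge_filter",
    "assemble_features",
]


def canonical_pair(u: str, v: str) -> tuple[str, str]:
    u, v = str(u).strip(), str(v).strip()
    return (u, v) if u <= v else (v, u)


@dataclass
class InteractionNetwork:
    """Ordered list of unordered gene pairs; edge i is ``edges[i]``."""

    edges: list[tuple[str, str]]

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValidationError(f"self-loop edge ({u}, {v})")
        if len(set(self.edges)) != len(self.edges):
            raise ValidationError("duplicate edges after canonical ordering")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "InteractionNetwork":
        """Build a network from raw pairs, dropping self-loops and duplicates.

        Pairs are canonicalised (lexicographic order within the pair); the
        first occurrence fixes an edge's index.
        """
        seen: set[tuple[str, str]] = set()
        edges: list[tuple[str, str]] = []
        for u, v in pairs:
            pair = canonical_pair(u, v)
            if pair[0] == pair[1] or pair in seen:
                continue
            seen.add(pair)
            edges.append(pair)
        return cls(edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def genes(self) -> set[str]:
        return {g for e in self.edges for g in e}


@dataclass
class MassActionParams:
    """Law-of-mass-action constants: affinity = alpha * [u]**a * [v]**b."""

    reaction_constant: float = 1.0
    stoich_u: float = 1.0
    stoich_v: float = 1.0

    def __post_init__(self) -> None:
        if min(self.reaction_constant, self.stoich_u, self.stoich_v) <= 0:
            raise ValidationError("mass-action constants must be positive")


@dataclass
class AffinityMatrix:
    """Samples x edges matrix of mass-action affinities a_ji."""

    values: np.ndarray  # shape (n_samples, n_edges)
    network: InteractionNetwork
    params: MassActionParams = field(default_factory=MassActionParams)


@dataclass
class CoexpressionWeights:
    """Per-edge co-expression coefficients B, before and after the cutoff."""

    raw: np.ndarray
    network: InteractionNetwork
    formula_mode: str = "standard"
    thresholded: np.ndarray | None = None
    cutoff: float | None = None
    absolute: bool = False
    degenerate_edges: list[int] = field(default_factory=list)


@dataclass
class ClassSpec:
    """Class partition plus per-class centroids of edge and node features."""

    classes: list[str]
    member_sets: dict[str, np.ndarray]  # class -> sample indices
    sizes: dict[str, int]
    edge_centroids: np.ndarray  # (n_classes, n_edges)
    node_centroids: np.ndarray  # (n_classes, n_genes)


@dataclass
class FeatureSystem:
    """Joint edge + node feature system consumed by the LP.

    ``edge_affinity`` holds the affinity columns of the edges surviving the
    co-expression cutoff (their thresholded ``B`` in ``edge_coexpression``);
    ``node_expression`` holds expression columns for the candidate node
    genes. ``edge_src_idx`` / ``node_src_idx`` map columns back to the full
    affinity matrix / expression matrix they were sliced from.
    """

    sample_ids: list[str]
    edge_pairs: list[tuple[str, str]]
    edge_affinity: np.ndarray  # (m, p)
    edge_coexpression: np.ndarray  # (p,)
    edge_src_idx: np.ndarray
    node_genes: list[str]
    node_expression: np.ndarray  # (m, n)
    node_src_idx: np.ndarray

    @property
    def n_edges(self) -> int:
        return len(self.edge_pairs)

    @property
    def n_nodes(self) -> int:
        return len(self.node_genes)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def feature_names(self) -> list[str]:
        return [f"{u}--{v}" for u, v in self.edge_pairs] + list(self.node_genes)


def mass_action_affinity(
    expr: ExpressionMatrix,
    net: InteractionNetwork,
    params: MassActionParams | None = None,
) -> AffinityMatrix:
    """Per-sample affinity of every edge: alpha * x_u**a * x_v**b.

    With default parameters this is the elementwise product of the two
    endpoint genes' expression vectors.
    """
    params = params or MassActionParams()
    gene_pos = expr.gene_index()
    for u, v in net.edges:
        if u not in gene_pos or v not in gene_pos:
            raise ValidationError(
                f"edge ({u}, {v}) references a gene absent from the expression matrix"
            )
    if net.n_edges == 0:
        return AffinityMatrix(np.zeros((expr.n_samples, 0)), net, params)
    u_idx = np.asarray([gene_pos[u] for u, _ in net.edges])
    v_idx = np.asarray([gene_pos[v] for _, v in net.edges])
    xu = expr.values[u_idx, :].T  # (m, p)
    xv = expr.values[v_idx, :].T
    vals = params.reaction_constant * xu**params.stoich_u * xv**params.stoich_v
    return AffinityMatrix(vals, net, params)


def class_centroids(
    aff: AffinityMatrix,
    expr: ExpressionMatrix,
    labels: Mapping[str, str] | None = None,
) -> ClassSpec:
    """Per-class mean affinity (a_ik) and mean expression (x_ik).

    ``labels`` defaults to the labels carried by ``expr``.
    """
    if labels is not None:
        expr = ExpressionMatrix(
            expr.gene_ids, expr.sample_ids, expr.values, dict(labels)
        )
    members = expr.class_members()
    for cls, idx in members.items():
        if idx.size == 0:
            raise ValidationError(f"class {cls!r} is empty")
    classes = sorted(members)
    edge_cent = np.stack(
        [aff.values[members[c], :].mean(axis=0) for c in classes]
    ) if aff.values.shape[1] else np.zeros((len(classes), 0))
    node_cent = np.stack([expr.values[:, members[c]].mean(axis=1) for c in classes])
    return ClassSpec(
        classes=classes,
        member_sets=members,
        sizes={c: int(members[c].size) for c in classes},
        edge_centroids=edge_cent,
        node_centroids=node_cent,
    )


def _spearman_from_ranks(ru: np.ndarray, rv: np.ndarray, denominator: str) -> float:
    m = ru.size
    d2 = float(((ru - rv) ** 2).sum())
    if denominator == "standard":
        return 1.0 - 6.0 * d2 / (m * (m**2 - 1))
    return 1.0 - 6.0 * d2 / (m * (m - 1))


def spearman_coexpression(
    expr: ExpressionMatrix,
    net: InteractionNetwork,
    formula_mode: str = "standard",
    scope: str = "pooled",
) -> CoexpressionWeights:
    """Rank-correlation co-expression coefficient B for every edge.

    ``formula_mode="standard"`` uses the usual rank-difference denominator
    ``m (m^2 - 1)``, guaranteeing B in [-1, 1]; ``"legacy"`` uses
    ``m (m - 1)``, which for m >= 3 can leave that range and is provided for
    exact replication only. Ties receive average ranks.

    ``scope="pooled"`` ranks across all m samples; ``scope="per_class_max"``
    computes B within each class (requires labels) and keeps the maximum --
    an edge then counts as co-expressed if it is strongly co-expressed in at
    least one context, which keeps differentially co-expressed pairs visible.

    A constant gene makes B undefined; the edge's raw weight is set to 0 and
    recorded in ``degenerate_edges`` alongside a warning.
    """
    if formula_mode not in ("standard", "legacy"):
        raise ValidationError(f"unknown formula_mode {formula_mode!r}")
    if scope not in ("pooled", "per_class_max"):
        raise ValidationError(f"unknown scope {scope!r}")
    if expr.n_samples < 3:
        raise ValidationError("co-expression needs at least 3 samples")

    gene_pos = expr.gene_index()
    if scope == "pooled":
        blocks = [np.arange(expr.n_samples)]
    else:
        blocks = [idx for _, idx in sorted(expr.class_members().items())]
        for idx in blocks:
            if idx.size < 3:
                raise ValidationError(
                    "per-class co-expression needs >= 3 samples per class"
                )

    raw = np.zeros(net.n_edges)
    degenerate: list[int] = []
    for block in blocks:
        sub = expr.values[:, block]
        ranks = rankdata(sub, axis=1)  # average ranks for ties
        for i, (u, v) in enumerate(net.edges):
            ru, rv = ranks[gene_pos[u]], ranks[gene_pos[v]]
            if np.ptp(sub[gene_pos[u]]) == 0 or np.ptp(sub[gene_pos[v]]) == 0:
                b = 0.0
                if i not in degenerate:
                    degenerate.append(i)
            else:
                b = _spearman_from_ranks(ru, rv, formula_mode)
            if scope == "pooled":
                raw[i] = b
            else:
                raw[i] = b if block is blocks[0] else max(raw[i], b)
    if degenerate:
        warnings.warn(
            f"constant gene(s) made co-expression undefined for "
            f"{len(degenerate)} edge(s); their B was set to 0",
            stacklevel=2,
        )
    return CoexpressionWeights(
        raw=raw, network=net, formula_mode=formula_mode, degenerate_edges=degenerate
    )


def threshold_coexpression(
    weights: CoexpressionWeights, cutoff: float, absolute: bool = False
) -> CoexpressionWeights:
    """Apply the cutoff rule: B passes if B >= k, else it is set to 0.

    With ``absolute=True`` the magnitude is tested and kept (|B| >= k passes
    as |B|), so strongly anti-correlated pairs survive with a non-negative
    multiplier.
    """
    mag = np.abs(weights.raw) if absolute else weights.raw
    thr = np.where(mag >= cutoff, mag, 0.0)
    return CoexpressionWeights(
        raw=weights.raw.copy(),
        network=weights.network,
        formula_mode=weights.formula_mode,
        thresholded=thr,
        cutoff=float(cutoff),
        absolute=absolute,
        degenerate_edges=list(weights.degenerate_edges),
    )


def anchor_edge_filter(
    net: InteractionNetwork, anchors: Iterable[str]
) -> InteractionNetwork:
    """Keep only edges with at least one endpoint in ``anchors``.

    Typical use: restrict the PPI network to edges touching differentially
    expressed transcription factors. Edge order (hence indexing) follows the
    original network.
    """
    anchors = {str(a).strip() for a in anchors}
    if not anchors:
        raise ValidationError("anchor set is empty; nothing would anchor")
    kept = [e for e in net.edges if e[0] in anchors or e[1] in anchors]
    if not kept:
        warnings.warn("anchor set is disjoint from all edges; network is empty",
                      stacklevel=2)
    return InteractionNetwork(kept)


def assemble_features(
    aff: AffinityMatrix,
    weights: CoexpressionWeights,
    expr: ExpressionMatrix,
    node_gene_list: Sequence[str] | None = None,
) -> FeatureSystem:
    """Combine surviving edge features and node features into one system.

    Edges whose thresholded B is 0 are dropped: their LP constraint
    coefficients would be identically zero, so their weight could only be 0.
    ``node_gene_list`` defaults to every gene in ``expr``.
    """
    if weights.thresholded is None:
        raise ValidationError("co-expression weights are not thresholded yet")
    if weights.network is not aff.network and weights.network.edges != aff.network.edges:
        raise ValidationError("affinity and co-expression refer to different networks")
    gene_pos = expr.gene_index()
    node_genes = list(node_gene_list) if node_gene_list is not None else list(
        expr.gene_ids
    )
    missing = [g for g in node_genes if g not in gene_pos]
    if missing:
        raise ValidationError(f"node genes absent from expression matrix: {missing}")
    edge_src = np.flatnonzero(weights.thresholded != 0)
    node_src = np.asarray([gene_pos[g] for g in node_genes], dtype=int)
    return FeatureSystem(
        sample_ids=list(expr.sample_ids),
        edge_pairs=[aff.network.edges[i] for i in edge_src],
        edge_affinity=aff.values[:, edge_src],
        edge_coexpression=weights.thresholded[edge_src],
        edge_src_idx=edge_src,
        node_genes=node_genes,
        node_expression=expr.values[node_src, :].T,
        node_src_idx=node_src,
    )
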