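"""Cross-validated classification on selected biomarkers, plus baselines.

The downstream classifier is a binomial generalized linear model (logistic
regression with intercept) fitted on the selected features -- node features
are expression columns, edge features are B-weighted expression products
(the context-specific affinity). Performance is summarised by sensitivity,
specificity and accuracy from the pooled out-of-fold confusion table and by
the rank-based (Mann-Whitney) AUC of the pooled out-of-fold scores.

Two cross-validation protocols are provided. ``mode="preselect"`` selects the
biomarkers once on the full dataset and only cross-validates the classifier
-- the protocol customarily reported with this family of selectors, which
leaks selection information into the folds. ``mode="nested"`` re-runs the
selector inside every training fold and is the honest estimate; on weak
signal its AUC is systematically below the preselect-mode AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Sequence, Union

import numpy as np
from scipy.stats import ttest_ind
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .features import canonical_pair
from .io import ExpressionMatrix, ValidationError
from .lp import BiomarkerSet

__all__ = [
    "ConfusionMetrics",
    "CVResult",
    "UndefinedMetricError",
    "FeatureDef",
    "confusion_metrics",
    "auroc",
    "glm_classifier",
    "design_matrix",
    "biomarkers_to_features",
    "kfold_evaluate",
    "ttest_selector",
]

# ("node", gene) or ("edge", (u, v), B)
FeatureDef = Union[tuple[str, str], tuple[str, tuple[str, str], float]]


class UndefinedMetricError(ValueError):
    """A confusion-metric denominator is zero."""


@dataclass
class ConfusionMetrics:
    TP: int
    TN: int
    FP: int
    FN: int
    Sn: float
    Sp: float
    ACC: float


def confusion_metrics(TP: int, TN: int, FP: int, FN: int) -> ConfusionMetrics:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy.

    Computed in exact rational arithmetic before conversion to float; a zero
    denominator raises :class:`UndefinedMetricError`.
    """
    for name, v in (("TP", TP), ("TN", TN), ("FP", FP), ("FN", FN)):
        if v < 0 or int(v) != v:
            raise ValidationError(f"{name} must be a non-negative integer")
    if TP + FN == 0:
        raise UndefinedMetricError("Sn undefined: no positive samples (TP+FN=0)")
    if TN + FP == 0:
        raise UndefinedMetricError("Sp undefined: no negative samples (TN+FP=0)")
    sn = Fraction(TP, TP + FN)
    sp = Fraction(TN, TN + FP)
    acc = Fraction(TP + TN, TP + TN + FP + FN)
    return ConfusionMetrics(
        TP=int(TP), TN=int(TN), FP=int(FP), FN=int(FN),
        Sn=float(sn), Sp=float(sp), ACC=float(acc),
    )


def auroc(scores: Sequence[float], labels: Sequence, pos_label=None) -> float:
    """Rank-based (Mann-Whitney) AUC with tie correction.

    ``pos_label`` defaults to the lexicographically larger of the two
    labels.
    """
    labels = [str(x) for x in labels]
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValidationError(f"AUC needs exactly two classes, got {classes}")
    pos = str(pos_label) if pos_label is not None else classes[-1]
    if pos not in classes:
        raise ValidationError(f"pos_label {pos!r} not among labels {classes}")
    y = np.asarray([1 if lab == pos else 0 for lab in labels])
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def glm_classifier(
    X: np.ndarray,
    y: Sequence,
    pos_label=None,
    ridge: float = 1e-4,
) -> Callable[[np.ndarray], np.ndarray]:
    """Fit a binomial GLM (logistic regression with intercept) scorer.

    Features are standardized to the training mean/SD (a monotone affine
    map, so AUC is unaffected) and a small L2 ridge of strength ``ridge``
    stabilizes the fit under perfect separation instead of diverging.
    Returns a scorer mapping a samples x features array to probabilities of
    the positive class (default: lexicographically larger label).
    """
    X = np.asarray(X, dtype=float)
    y = [str(v) for v in y]
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValidationError(f"binary classifier needs two classes, got {classes}")
    if min(y.count(c) for c in classes) < 2:
        raise ValidationError("need >= 2 training samples per class")
    pos = str(pos_label) if pos_label is not None else classes[-1]
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0  # constant feature: leave centred at zero
    model = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=5000)
    model.fit((X - mean) / sd, np.asarray([1 if v == pos else 0 for v in y]))
    pos_col = int(np.flatnonzero(model.classes_ == 1)[0])

    def scorer(X_new: np.ndarray) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        return model.predict_proba((X_new - mean) / sd)[:, pos_col]

    return scorer


def design_matrix(expr: ExpressionMatrix, features: Sequence[FeatureDef]) -> np.ndarray:
    """Samples x features design: expression for nodes, B * x_u * x_v for edges."""
    gene_pos = expr.gene_index()
    cols = []
    for f in features:
        if f[0] == "node":
            cols.append(expr.values[gene_pos[f[1]], :])
        elif f[0] == "edge":
            (u, v), b = f[1], float(f[2])
            cols.append(b * expr.values[gene_pos[u], :] * expr.values[gene_pos[v], :])
        else:
            raise ValidationError(f"unknown feature kind {f[0]!r}")
    if not cols:
        raise ValidationError("empty feature list")
    return np.column_stack(cols)


def biomarkers_to_features(bset: BiomarkerSet) -> list[FeatureDef]:
    feats: list[FeatureDef] = [
        ("edge", canonical_pair(*e.genes), e.coexpression) for e in bset.edge_biomarkers
    ]
    feats += [("node", nb.gene) for nb in bset.node_biomarkers]
    return feats


@dataclass
class CVResult:
    """Out-of-fold evaluation summary.

    ``pooled`` aggregates every sample's single out-of-fold prediction into
    one confusion table (score >= threshold -> positive); ``auc`` is the
    Mann-Whitney AUC of the pooled scores.
    """

    fold_assignments: np.ndarray
    per_fold: list[ConfusionMetrics | None]
    pooled: ConfusionMetrics
    auc: float
    scores: np.ndarray
    mode: str
    seed: int
    k_folds: int
    classifier: str = "binomial GLM (logistic regression, ridge-stabilized)"
    pos_label: str = ""


def kfold_evaluate(
    expr: ExpressionMatrix,
    feature_spec: Sequence[FeatureDef] | Callable[[ExpressionMatrix], Sequence[FeatureDef]],
    k_folds: int = 10,
    seed: int = 0,
    mode: str = "preselect",
    pos_label=None,
    threshold: float = 0.5,
) -> CVResult:
    """Stratified k-fold cross-validation of the GLM on selected features.

    ``feature_spec`` is either a fixed feature list or a selector callable.
    In ``mode="preselect"`` a callable is invoked once on the full dataset
    before cross-validation (selection leakage, as conventionally reported);
    in ``mode="nested"`` it is re-invoked on each training fold.
    """
    if mode not in ("preselect", "nested"):
        raise ValidationError(f"unknown mode {mode!r}")
    if expr.labels is None:
        raise ValidationError("expression matrix carries no class labels")
    classes = expr.classes
    if len(classes) != 2:
        raise ValidationError("cross-validated evaluation supports two classes")
    y = np.asarray([expr.labels[s] for s in expr.sample_ids])
    min_class = min((y == c).sum() for c in classes)
    if k_folds > min_class:
        raise ValidationError(
            f"k_folds={k_folds} exceeds the smallest class size {min_class}; "
            "stratified folds would lack a class"
        )
    pos = str(pos_label) if pos_label is not None else classes[-1]

    if not callable(feature_spec):
        fixed: Sequence[FeatureDef] | None = list(feature_spec)
    elif mode == "preselect":
        fixed = list(feature_spec(expr))
    else:
        fixed = None

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    m = expr.n_samples
    scores = np.full(m, np.nan)
    assignments = np.full(m, -1)
    per_fold: list[ConfusionMetrics | None] = []
    for fold, (train, test) in enumerate(skf.split(np.zeros(m), y)):
        assignments[test] = fold
        expr_train = expr.subset_samples(train)
        feats = fixed if fixed is not None else list(feature_spec(expr_train))
        X_train = design_matrix(expr_train, feats)
        scorer = glm_classifier(X_train, y[train], pos_label=pos)
        X_test = design_matrix(expr.subset_samples(test), feats)
        scores[test] = scorer(X_test)
        per_fold.append(_fold_metrics(scores[test], y[test], pos, threshold))

    pooled = _fold_metrics(scores, y, pos, threshold, strict=True)
    assert pooled is not None
    return CVResult(
        fold_assignments=assignments,
        per_fold=per_fold,
        pooled=pooled,
        auc=auroc(scores, y, pos_label=pos),
        scores=scores,
        mode=mode,
        seed=seed,
        k_folds=k_folds,
        pos_label=pos,
    )


def _fold_metrics(scores, y, pos, threshold, strict=False):
    pred_pos = np.asarray(scores) >= threshold
    is_pos = np.asarray(y) == pos
    tp = int((pred_pos & is_pos).sum())
    tn = int((~pred_pos & ~is_pos).sum())
    fp = int((pred_pos & ~is_pos).sum())
    fn = int((~pred_pos & is_pos).sum())
    try:
        return confusion_metrics(tp, tn, fp, fn)
    except UndefinedMetricError:
        if strict:
            raise
        return None


def ttest_selector(
    expr: ExpressionMatrix,
    p_threshold: float | None = 5e-5,
    top_k: int | None = None,
) -> list[str]:
    """Welch two-sample t-test gene selector.

    Returns genes with p < ``p_threshold`` (default 5e-5, the conventional
    strict array threshold); with ``top_k`` set, the k smallest-p genes are
    returned instead. Genes are ordered by ascending p-value.
    """
    if expr.labels is None:
        raise ValidationError("expression matrix carries no class labels")
    classes = expr.classes
    if len(classes) != 2:
        raise ValidationError("t-test selector supports exactly two classes")
    members = expr.class_members()
    for c, idx in members.items():
        if idx.size < 2:
            raise ValidationError(f"class {c!r} has < 2 samples")
    a = expr.values[:, members[classes[0]]]
    b = expr.values[:, members[classes[1]]]
    pvals = ttest_ind(a, b, axis=1, equal_var=False).pvalue
    pvals = np.nan_to_num(pvals, nan=1.0)  # constant genes are never selected
    order = np.argsort(pvals, kind="stable")
    if top_k is not None:
        return [expr.gene_ids[i] for i in order[: int(top_k)]]
    return [expr.gene_ids[i] for i in order if pvals[i] < float(p_threshold)]
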