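"""Reading, writing and pre-filtering of expression matrices and companion files.

Expression matrices are delimited text (TSV or CSV by extension), one header
row of sample identifiers and a first column of gene identifiers; an
orientation flag accepts the transposed layout. Class labels come as a
two-column ``sample_id<TAB>class`` file, PPI edges as a two-column edge list
(BioGRID tab-export symbol columns work via the column arguments), anchor
genes one per line.

Three gene filters are provided, mirroring the usual pre-processing applied
before network-based feature construction: removal of genes with missing
values, removal of low-information genes by Shannon entropy of the binned
expression distribution, and removal of genes whose replicate max/min
expression ratio exceeds a bound (default 100, the conventional TPM
reproducibility rule).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ParseError",
    "EmptyResultError",
    "ExpressionMatrix",
    "FilterReport",
    "read_expression",
    "write_expression",
    "read_labels",
    "read_edge_list",
    "read_anchor_genes",
    "filter_missing",
    "entropy_filter",
    "gene_entropies",
    "replicate_ratio_filter",
]

MISSING_TOKENS = ("", "NA", "NaN", "nan", "NAN", "na", "null", "NULL")


class ValidationError(ValueError):
    """Input violates a structural contract (duplicates, unknown IDs, ...)."""


class ParseError(ValueError):
    """File is malformed at a specific location."""


class EmptyResultError(ValueError):
    """A filter removed every gene."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative expression values.

    ``values[i, j]`` is the expression of ``gene_ids[i]`` in
    ``sample_ids[j]``. ``labels`` (optional) maps every sample to its class;
    when present, every sample must be labelled and every class non-empty.
    Missing entries are represented as NaN until :func:`filter_missing` runs.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if ids.count(x) > 1})
                raise ValidationError(f"duplicated {name} identifiers: {dupes}")
        if self.labels is not None:
            self.labels = {str(k): str(v) for k, v in self.labels.items()}
            missing = [s for s in self.sample_ids if s not in self.labels]
            if missing:
                raise ValidationError(f"samples without a class label: {missing}")
            self.labels = {s: self.labels[s] for s in self.sample_ids}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def classes(self) -> list[str]:
        """Sorted distinct class labels (requires labels)."""
        if self.labels is None:
            raise ValidationError("expression matrix carries no class labels")
        return sorted(set(self.labels.values()))

    def class_members(self) -> dict[str, np.ndarray]:
        """Class label -> array of sample indices (column positions)."""
        members: dict[str, list[int]] = {}
        if self.labels is None:
            raise ValidationError("expression matrix carries no class labels")
        for j, s in enumerate(self.sample_ids):
            members.setdefault(self.labels[s], []).append(j)
        return {k: np.asarray(v, dtype=int) for k, v in sorted(members.items())}

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, keep: Sequence[int]) -> "ExpressionMatrix":
        keep = list(keep)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in keep],
            list(self.sample_ids),
            self.values[keep, :],
            dict(self.labels) if self.labels is not None else None,
        )

    def subset_samples(self, keep: Sequence[int]) -> "ExpressionMatrix":
        keep = list(keep)
        samples = [self.sample_ids[j] for j in keep]
        labels = (
            {s: self.labels[s] for s in samples} if self.labels is not None else None
        )
        return ExpressionMatrix(
            list(self.gene_ids), samples, self.values[:, keep], labels
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class FilterReport:
    """Outcome of one gene-filtering rule."""

    rule: str  # one of {"missing", "entropy", "replicate_ratio"}
    genes_removed: int
    genes_kept: int
    parameters: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "rule": self.rule,
                "genes_removed": self.genes_removed,
                "genes_kept": self.genes_kept,
                "parameters": self.parameters,
            }
        )


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _check_rectangular(path: Path, sep: str) -> None:
    # pandas NaN-fills short rows, which would be indistinguishable from a
    # legitimate missing value; enforce a rectangular layout up front.
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        header = next(reader, None)
        if header is None:
            raise ParseError(f"{path}: file is empty")
        width = len(header)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            # header may or may not name the index column
            if len(row) not in (width, width + 1):
                raise ParseError(
                    f"{path}: row {lineno} has {len(row)} fields, expected "
                    f"{width} or {width + 1}"
                )


def read_expression(
    path: str | Path,
    samples_as_rows: bool = False,
    labels: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression matrix.

    Parameters
    ----------
    path:
        TSV (default) or CSV (by ``.csv`` extension). Header row holds sample
        IDs, first column holds gene IDs; set ``samples_as_rows`` for the
        transposed layout.
    labels:
        Optional sample -> class mapping attached to the result.
    """
    path = Path(path)
    sep = _sep_for(path)
    _check_rectangular(path, sep)
    try:
        frame = pd.read_csv(
            path,
            sep=sep,
            header=0,
            index_col=0,
            na_values=list(MISSING_TOKENS),
            keep_default_na=True,
        )
    except pd.errors.ParserError as exc:  # pragma: no cover - guarded above
        raise ParseError(f"{path}: {exc}") from exc
    for col in frame.columns:
        if frame[col].dtype == object:
            try:
                frame[col] = pd.to_numeric(frame[col])
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"{path}: non-numeric value in column {col!r}: {exc}"
                ) from exc
    if samples_as_rows:
        frame = frame.T
    gene_ids = [str(g).strip() for g in frame.index]
    sample_ids = [str(s).strip() for s in frame.columns]
    return ExpressionMatrix(
        gene_ids,
        sample_ids,
        frame.to_numpy(dtype=float),
        dict(labels) if labels is not None else None,
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep=_sep_for(path), index_label="gene_id")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample_id<TAB>class`` file (header optional)."""
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if frame.shape[1] < 2:
        raise ParseError(f"{path}: expected two tab-separated columns")
    if str(frame.iloc[0, 0]).lower() in ("sample", "sample_id", "id"):
        frame = frame.iloc[1:]
    return {
        str(s).strip(): str(c).strip()
        for s, c in zip(frame.iloc[:, 0], frame.iloc[:, 1])
    }


def read_edge_list(
    path: str | Path,
    column_u: int | str = 0,
    column_v: int | str = 1,
) -> list[tuple[str, str]]:
    """Read gene pairs from a delimited edge list.

    Integer columns address a headerless two-plus-column file; string columns
    address a file with a header row (e.g. BioGRID's official symbol columns).
    """
    by_name = isinstance(column_u, str) or isinstance(column_v, str)
    frame = pd.read_csv(
        path, sep="\t", header=0 if by_name else None, dtype=str, comment="#"
    )
    try:
        u_col = frame[column_u] if by_name else frame.iloc[:, int(column_u)]
        v_col = frame[column_v] if by_name else frame.iloc[:, int(column_v)]
    except (KeyError, IndexError) as exc:
        raise ParseError(f"{path}: edge columns {column_u!r}/{column_v!r}: {exc}")
    return [
        (str(u).strip(), str(v).strip())
        for u, v in zip(u_col, v_col)
        if not (pd.isna(u) or pd.isna(v))
    ]


def read_anchor_genes(path: str | Path) -> set[str]:
    """Read a one-gene-per-line anchor list (e.g. differentially expressed TFs)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def _kept(expr: ExpressionMatrix, keep: np.ndarray, rule: str, params: dict):
    keep_idx = np.flatnonzero(keep)
    if keep_idx.size == 0:
        raise EmptyResultError(f"{rule} filter removed every gene")
    report = FilterReport(
        rule=rule,
        genes_removed=int(expr.n_genes - keep_idx.size),
        genes_kept=int(keep_idx.size),
        parameters=params,
    )
    return expr.subset_genes(keep_idx), report


def filter_missing(expr: ExpressionMatrix) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop every gene with at least one missing (NaN) entry."""
    keep = ~np.isnan(expr.values).any(axis=1)
    return _kept(expr, keep, "missing", {})


def gene_entropies(values: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Shannon entropy (bits) of each gene's equal-width binned distribution.

    Bins span each gene's own [min, max]; a constant gene has entropy 0.
    """
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    values = np.asarray(values, dtype=float)
    out = np.zeros(values.shape[0])
    for i, row in enumerate(values):
        lo, hi = np.nanmin(row), np.nanmax(row)
        if not hi > lo:
            continue  # constant gene: entropy 0
        counts, _ = np.histogram(row[~np.isnan(row)], bins=n_bins, range=(lo, hi))
        p = counts[counts > 0] / counts.sum()
        out[i] = float(-(p * np.log2(p)).sum())
    return out


def entropy_filter(
    expr: ExpressionMatrix,
    n_bins: int = 10,
    min_entropy: float | None = None,
    fraction: float = 0.10,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Remove low-information genes by expression-distribution entropy.

    With ``min_entropy`` given, genes with entropy strictly below it are
    removed (idempotent). Otherwise the lowest-entropy ``fraction`` of genes
    is removed (a relative rule; re-applying removes another slice).
    """
    ent = gene_entropies(expr.values, n_bins=n_bins)
    if min_entropy is not None:
        keep = ent >= float(min_entropy)
        params = {"n_bins": n_bins, "min_entropy": float(min_entropy)}
    else:
        n_drop = int(math.floor(fraction * expr.n_genes))
        order = np.argsort(ent, kind="stable")
        keep = np.ones(expr.n_genes, dtype=bool)
        keep[order[:n_drop]] = False
        params = {"n_bins": n_bins, "fraction": fraction}
    return _kept(expr, keep, "entropy", params)


def replicate_ratio_filter(
    expr: ExpressionMatrix,
    replicate_groups: Mapping[str, Sequence[str]],
    max_ratio: float = 100.0,
    pseudocount: float = 0.0,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Remove genes whose replicate max/min ratio exceeds ``max_ratio``.

    A gene is removed if (max + pseudocount) / (min + pseudocount) >
    ``max_ratio`` within any replicate group. A group whose values are all
    zero (with zero pseudocount) counts as ratio 1 and is kept.
    """
    sample_pos = {s: j for j, s in enumerate(expr.sample_ids)}
    keep = np.ones(expr.n_genes, dtype=bool)
    for group, samples in replicate_groups.items():
        if len(samples) < 2:
            raise ValidationError(f"replicate group {group!r} has < 2 samples")
        unknown = [s for s in samples if s not in sample_pos]
        if unknown:
            raise ValidationError(
                f"replicate group {group!r} references unknown samples: {unknown}"
            )
        cols = [sample_pos[s] for s in samples]
        block = expr.values[:, cols]
        hi = block.max(axis=1) + pseudocount
        lo = block.min(axis=1) + pseudocount
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(hi == lo, 1.0, hi / np.where(lo == 0, np.nan, lo))
        keep &= ~(np.nan_to_num(ratio, nan=np.inf) > max_ratio)
    return _kept(
        expr,
        keep,
        "replicate_ratio",
        {"max_ratio": max_ratio, "pseudocount": pseudocount},
    )
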