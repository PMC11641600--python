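"""Binned, depth- and length-normalized histone signal around TSSs.

For each gene the window [TSS - flank, TSS + flank) is tiled by ``n_bins``
half-open, 0-based bins of equal width L_j, ordered 5'->3' in *transcript*
orientation (for minus-strand genes bin 1 is the genomically rightmost).
Aligned fragments (BED records) are counted by the midpoint rule -- each
fragment falls in exactly one bin, boundary midpoints go to the right bin --
giving raw counts h_ijlk (gene i, bin j, sample l, mark k). The normalized
signal is

    H_ijlk = h_ijlk * 1e9 / (h_kl * L_j)

with h_kl the sample's sequencing depth (total fragments in its BED file),
and H_ijk averages H_ijlk over samples. The two customary layouts are
5 kb flanks / 100 bins and 3 kb flanks / 60 bins (100-bp bins in both).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ParseError, ValidationError

__all__ = [
    "BinLayout",
    "BinnedSignal",
    "make_bin_layout",
    "read_bed_fragments",
    "read_tss_bed",
    "count_fragments",
    "normalize_signal",
    "tss_profile",
]


@dataclass
class BinLayout:
    """Bin grid around one gene's TSS.

    ``starts`` are genomic bin starts in ascending genomic order;
    ``transcript_order`` maps transcript-orientation bin j (0-based) to the
    genomic bin index. Windows extending below position 0 are clipped and
    the number of lost bins recorded in ``n_clipped`` (clipped bins keep
    their slot with zero coverage).
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    flank: int
    n_bins: int
    bin_width: int
    starts: np.ndarray
    transcript_order: np.ndarray
    n_clipped: int = 0

    @property
    def window(self) -> tuple[int, int]:
        return (self.tss - self.flank, self.tss + self.flank)


def make_bin_layout(
    gene_id: str, chrom: str, tss: int, strand: str, flank: int, n_bins: int
) -> BinLayout:
    """Tile [TSS - flank, TSS + flank) with ``n_bins`` equal half-open bins.

    ``n_bins`` must be even and ``flank`` divisible by ``n_bins / 2`` so the
    bin width is integral. Minus-strand genes get reversed bin order so that
    bin 1 is the most upstream bin in transcript orientation.
    """
    if n_bins <= 0 or n_bins % 2:
        raise ValidationError("n_bins must be a positive even integer")
    if flank <= 0 or flank % (n_bins // 2):
        raise ValidationError("flank must be a positive multiple of n_bins/2")
    if strand not in ("+", "-"):
        raise ValidationError(f"strand must be '+' or '-', got {strand!r}")
    width = 2 * flank // n_bins
    left = tss - flank
    starts = left + width * np.arange(n_bins)
    n_clipped = int(((starts + width) <= 0).sum()) if left < 0 else 0
    order = np.arange(n_bins) if strand == "+" else np.arange(n_bins)[::-1]
    return BinLayout(
        gene_id=gene_id,
        chrom=str(chrom),
        tss=int(tss),
        strand=strand,
        flank=int(flank),
        n_bins=int(n_bins),
        bin_width=int(width),
        starts=starts,
        transcript_order=order,
        n_clipped=n_clipped,
    )


def read_bed_fragments(path: str | Path) -> pd.DataFrame:
    """Read a 3+-column BED of aligned fragments (chrom, start, end)."""
    frame = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={"chrom": str}, skip_blank_lines=True,
    )
    if frame.empty:
        return frame
    try:
        frame["start"] = frame["start"].astype(int)
        frame["end"] = frame["end"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-integer BED coordinates: {exc}") from exc
    return frame


def read_tss_bed(path: str | Path) -> pd.DataFrame:
    """Read a 6-column BED of TSS coordinates (strand required).

    The TSS is the ``start`` coordinate for plus-strand records and
    ``end - 1`` for minus-strand records (0-based).
    """
    frame = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    if frame["strand"].isna().any() or not frame["strand"].isin(["+", "-"]).all():
        raise ParseError(f"{path}: strand column is required and must be +/-")
    frame["tss"] = np.where(
        frame["strand"] == "+", frame["start"].astype(int), frame["end"].astype(int) - 1
    )
    return frame


def layouts_from_tss(
    tss_table: pd.DataFrame, flank: int, n_bins: int
) -> list[BinLayout]:
    return [
        make_bin_layout(row.name, row.chrom, int(row.tss), row.strand, flank, n_bins)
        for row in tss_table.itertuples(index=False)
    ]


def count_fragments(
    fragments: pd.DataFrame, layouts: Sequence[BinLayout]
) -> np.ndarray:
    """Raw per-bin fragment counts, genes x bins in transcript order.

    A fragment is assigned to the single bin containing its midpoint
    ``(start + end) // 2``; bins are half-open so a midpoint on a boundary
    counts for the bin to its right. Fragment and TSS files whose chromosome
    names share nothing raise an error listing both name sets.
    """
    counts = np.zeros((len(layouts), layouts[0].n_bins if layouts else 0), dtype=int)
    if not layouts:
        return counts
    if len(fragments):
        frag_chroms = set(fragments["chrom"].unique())
        tss_chroms = {lo.chrom for lo in layouts}
        if not (frag_chroms & tss_chroms):
            raise ValidationError(
                "no chromosome shared between fragments and TSS records: "
                f"fragments {sorted(frag_chroms)} vs TSS {sorted(tss_chroms)}"
            )
        mids_by_chrom = {
            chrom: np.sort(
                ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2)
            )
            for chrom, sub in fragments.groupby("chrom")
        }
    else:
        mids_by_chrom = {}
    for gi, layout in enumerate(layouts):
        mids = mids_by_chrom.get(layout.chrom)
        if mids is None:
            continue
        edges = np.append(layout.starts, layout.starts[-1] + layout.bin_width)
        # half-open [edge_j, edge_{j+1}): side="right" puts boundary mids right
        pos = np.searchsorted(mids, edges, side="left")
        per_genomic_bin = np.diff(pos)
        counts[gi, :] = per_genomic_bin[layout.transcript_order]
    return counts


@dataclass
class BinnedSignal:
    """Raw and normalized binned signal for one mark.

    ``raw[sample]`` and ``normalized[sample]`` are genes x bins arrays in
    transcript orientation; ``averaged`` is the cross-sample mean of the
    normalized signal (H_ijk).
    """

    gene_ids: list[str]
    raw: dict[str, np.ndarray]
    normalized: dict[str, np.ndarray]
    averaged: np.ndarray
    depths: dict[str, int]
    bin_width: int


def normalize_signal(
    raw: Mapping[str, np.ndarray],
    depths: Mapping[str, int],
    layouts: Sequence[BinLayout],
    gene_ids: Sequence[str] | None = None,
) -> BinnedSignal:
    """Apply H = h * 1e9 / (depth * L_j) per sample and average over samples."""
    if set(raw) != set(depths):
        raise ValidationError("raw counts and depths name different samples")
    widths = {lo.bin_width for lo in layouts}
    if len(widths) != 1:
        raise ValidationError("mixed bin widths across genes")
    width = widths.pop()
    normalized = {}
    for sample, h in raw.items():
        depth = depths[sample]
        if depth <= 0:
            raise ValidationError(f"sample {sample!r} has non-positive depth")
        normalized[sample] = np.asarray(h, dtype=float) * 1e9 / (depth * width)
    samples = sorted(raw)
    averaged = np.mean([normalized[s] for s in samples], axis=0)
    return BinnedSignal(
        gene_ids=list(gene_ids or [lo.gene_id for lo in layouts]),
        raw={s: np.asarray(raw[s]) for s in samples},
        normalized=normalized,
        averaged=averaged,
        depths={s: int(depths[s]) for s in samples},
        bin_width=width,
    )


def tss_profile(
    fragment_paths: Mapping[str, str | Path],
    tss_path: str | Path,
    flank: int = 5000,
    n_bins: int = 100,
) -> BinnedSignal:
    """End-to-end profile: BED fragments per sample + TSS BED -> BinnedSignal.

    Sequencing depth per sample is the total number of fragments in its BED
    file.
    """
    tss_table = read_tss_bed(tss_path)
    layouts = layouts_from_tss(tss_table, flank, n_bins)
    raw: dict[str, np.ndarray] = {}
    depths: dict[str, int] = {}
    for sample, path in fragment_paths.items():
        frags = read_bed_fragments(path)
        raw[sample] = count_fragments(frags, layouts)
        depths[sample] = int(len(frags))
    return normalize_signal(raw, depths, layouts)
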