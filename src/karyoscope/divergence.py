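"""X-Y divergence summaries from heterozygous SNPs and Y-contig alignments.

Within the region of the X still shared with the Y, male reads carry both
gametologs, so X-Y divergence is visible directly as heterozygous SNP
density in males — no phasing or gametolog alignment is needed. This
module computes windowed het-SNP densities, cross-sample means, per-region
spacing summaries ("1 SNP every N bp"), and alignment coverage/identity of
Y contigs along the X.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import AlignmentRecord, GenomeWindows, HetSnpTable

__all__ = [
    "DensityTrack",
    "RegionDivergenceSummary",
    "AlignmentCoverageTrack",
    "snp_density",
    "mean_density",
    "region_summary",
    "format_spacing",
    "ycontig_coverage",
    "weighted_identity",
]


@dataclass
class DensityTrack:
    """Per-window SNP counts and densities (SNPs per bp) for one sample."""

    sample_id: str
    windows: GenomeWindows
    count: np.ndarray  # int for a single sample; float for averaged tracks
    density: np.ndarray

    def __post_init__(self) -> None:
        self.count = np.asarray(self.count)
        self.density = np.asarray(self.density, dtype=float)
        if self.count.shape != (len(self.windows),) or self.density.shape != self.count.shape:
            raise ValueError("track arrays must have one value per window")


def snp_density(snps: HetSnpTable, windows: GenomeWindows) -> DensityTrack:
    """Count het SNPs per window and divide by window length.

    Each SNP is counted in the window containing its (0-based) position;
    a SNP on an unknown chromosome or beyond the chromosome end is an
    error naming the offending record.
    """
    counts = np.zeros(len(windows), dtype=np.int64)
    for row in snps.table.itertuples(index=False):
        try:
            counts[windows.index(row.chrom, int(row.pos))] += 1
        except (KeyError, ValueError) as exc:
            raise ValueError(
                f"SNP {row.chrom}:{row.pos} ({row.ref}>{row.alt}) outside grid"
            ) from exc
    lengths = np.array([e - s for _, s, e in windows], dtype=float)
    return DensityTrack(snps.sample_id, windows, counts, counts / lengths)


def mean_density(tracks: Sequence[DensityTrack]) -> DensityTrack:
    """Per-window arithmetic mean density across samples (e.g. all males)."""
    if not tracks:
        raise ValueError("no tracks to average")
    grid = tracks[0].windows
    for t in tracks[1:]:
        if not t.windows.same_grid(grid):
            raise ValueError("density tracks are on different window grids")
    count = np.mean([t.count for t in tracks], axis=0)
    density = np.mean([t.density for t in tracks], axis=0)
    sample_id = "mean(" + ",".join(t.sample_id for t in tracks) + ")"
    return DensityTrack(sample_id, grid, count, density)


@dataclass(frozen=True)
class RegionDivergenceSummary:
    """SNP load of one region: totals, mean density and bp-per-SNP spacing."""

    chrom: str
    start: int
    end: int
    n_snps: int
    span: int
    mean_density: float
    spacing_bp: int | None  # None when the region holds no SNPs

    @property
    def sample_id(self) -> str | None:
        return getattr(self, "_sample_id", None)


def region_summary(
    snps: HetSnpTable, chrom: str, start: int, end: int
) -> RegionDivergenceSummary:
    """Average SNP density and spacing over one region.

    Spacing = span / n_snps, rounded half-up to the nearest bp; undefined
    (None) when the region contains no SNPs.
    """
    if end <= start:
        raise ValueError(f"zero-length region {chrom}:{start}-{end}")
    sub = snps.table
    in_region = (
        (sub["chrom"] == chrom) & (sub["pos"] >= start) & (sub["pos"] < end)
    )
    n = int(in_region.sum())
    span = end - start
    spacing = None
    if n > 0:
        spacing = int(
            (Decimal(span) / Decimal(n)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
        )
    return RegionDivergenceSummary(chrom, start, end, n, span, n / span, spacing)


def format_spacing(summary: RegionDivergenceSummary) -> str:
    """Human-readable spacing, e.g. '1 SNP every 2,215 bp'."""
    if summary.spacing_bp is None:
        return "no SNPs"
    return f"1 SNP every {summary.spacing_bp:,} bp"


@dataclass
class AlignmentCoverageTrack:
    """Fraction of each window covered by retained alignments, plus the
    length-weighted mean identity of those alignments."""

    windows: GenomeWindows
    fraction: np.ndarray
    weighted_mean_identity: float | None

    def __post_init__(self) -> None:
        self.fraction = np.asarray(self.fraction, dtype=float)
        if ((self.fraction < 0) | (self.fraction > 1)).any():
            raise ValueError("covered fractions must lie in [0, 1]")


def weighted_identity(alignments: Sequence[AlignmentRecord]) -> float | None:
    """Length-weighted mean percent identity: sum(id_i * len_i) / sum(len_i)."""
    if not alignments:
        return None
    total = sum(a.length for a in alignments)
    return sum(a.identity * a.length for a in alignments) / total


def ycontig_coverage(
    alignments: Sequence[AlignmentRecord], windows: GenomeWindows
) -> AlignmentCoverageTrack:
    """Per-window covered fraction of the target by Y-contig alignments.

    Overlapping alignment target intervals are unioned before computing
    covered bases (no double counting); the weighted mean identity,
    however, weights each alignment by its full length, mirroring the two
    separate summary formulas.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for a in alignments:
        if a.target_id not in windows.chrom_lengths:
            raise ValueError(f"alignment target {a.target_id!r} not in grid")
        if a.target_start < 0 or a.target_end > windows.chrom_lengths[a.target_id]:
            raise ValueError(
                f"alignment {a.query_id!r} exceeds bounds of {a.target_id!r}"
            )
        by_chrom.setdefault(a.target_id, []).append((a.target_start, a.target_end))
    covered = np.zeros(len(windows), dtype=float)
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts, ends = windows.bounds(chrom)
        off = windows.offset(chrom)
        for s, e in merged:
            first = windows.index(chrom, s)
            last = windows.index(chrom, e - 1)
            for w in range(first, last + 1):
                ws, we = starts[w - off], ends[w - off]
                covered[w] += max(0, min(e, we) - max(s, ws))
    lengths = np.array([e - s for _, s, e in windows], dtype=float)
    return AlignmentCoverageTrack(
        windows, covered / lengths, weighted_identity(list(alignments))
    )
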