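"""Sex-chromosome inference and X-Y shared-region calling from read depth.

Window depths are normalised by the median depth of autosomal windows, so
diploid regions sit at N ~ 1 and regions haploid in one sex at N ~ 0.5. In
an XX/X0 or XX/XY system the X is the chromosome with haploid coverage in
all males. Where a neo-Y exists (an X-autosome fusion whose unfused
homologue became male-limited), the part of the X still carried by the Y
shows *diploid* male coverage: those bins are found by the male-to-female
coverage ratio, merged across short gaps, and reported as shared regions
when long enough.

Females of viviparous filarial species can show sub-diploid X coverage
because gravid adults carry male and female embryos in utero; the
normalisation and classification thresholds here tolerate that dilution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_io import CoverageTrack, GenomeWindows

__all__ = [
    "NormalizedCoverageTrack",
    "PloidyThresholds",
    "XInference",
    "SharedRegion",
    "SharedRegionParams",
    "RegionCall",
    "normalize_coverage",
    "infer_x",
    "call_shared_regions",
    "region_length_mb",
    "render_region",
]


@dataclass
class NormalizedCoverageTrack(CoverageTrack):
    """A coverage track with window depths divided by the autosomal median."""

    N: np.ndarray = field(default=None)  # type: ignore[assignment]
    autosomal_median_depth: float = float("nan")

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.N is None:
            raise ValueError("normalized track requires N values")
        self.N = np.asarray(self.N, dtype=float)
        if self.N.shape != self.depth.shape:
            raise ValueError("N and depth must have identical shape")


def normalize_coverage(
    track: CoverageTrack, autosomes: Iterable[str]
) -> NormalizedCoverageTrack:
    """Divide each window depth by the median depth over autosomal windows."""
    autosomes = set(autosomes)
    if not autosomes:
        raise ValueError("autosome set is empty")
    mask = track.windows.chrom_mask(autosomes)
    if not mask.any():
        raise ValueError("no windows on the given autosomes")
    divisor = float(np.median(track.depth[mask]))
    if divisor <= 0:
        raise ValueError("degenerate coverage: autosomal median depth is 0")
    return NormalizedCoverageTrack(
        sample_id=track.sample_id,
        sex=track.sex,
        windows=track.windows,
        depth=track.depth,
        N=track.depth / divisor,
        autosomal_median_depth=divisor,
    )


@dataclass(frozen=True)
class PloidyThresholds:
    """Median-N cutpoints separating haploid, diploid and ambiguous calls.

    Expected N is 0.5 for haploid and 1.0 for diploid regions; the default
    boundaries (0.3 / 0.75 / 1.3) are midpoints with slack, wide enough
    that embryo-diluted female X coverage (~0.8) still classifies diploid.
    """

    haploid_min: float = 0.3
    haploid_max: float = 0.75  # exclusive; also diploid_min (inclusive)
    diploid_max: float = 1.3

    def classify(self, median_n: float) -> str:
        if self.haploid_min <= median_n < self.haploid_max:
            return "haploid"
        if self.haploid_max <= median_n <= self.diploid_max:
            return "diploid"
        return "ambiguous"


@dataclass
class XInference:
    """Result of X identification: per-sample ploidy calls and the X set."""

    x_chroms: frozenset[str]
    ploidy_calls: pd.DataFrame  # rows (sample_id, sex, chrom, median_N, call)
    normalized: dict[str, NormalizedCoverageTrack]  # by sample_id


def _per_chrom_median(track: CoverageTrack, values: np.ndarray) -> dict[str, float]:
    out = {}
    for chrom in track.windows.chrom_lengths:
        off = track.windows.offset(chrom)
        n = track.windows.n_windows(chrom)
        out[chrom] = float(np.median(values[off : off + n]))
    return out


def infer_x(
    tracks: Sequence[CoverageTrack],
    thresholds: PloidyThresholds = PloidyThresholds(),
) -> XInference:
    """Identify X chromosome(s) from sexed coverage tracks.

    The normalising divisor should exclude the X, but the X is not known
    a priori, so inference is two-pass: first normalise each track by the
    global median over all windows and provisionally call chromosomes
    haploid in every male as X; then renormalise by the median over the
    remaining (autosomal) windows and make the final calls. X = the set of
    chromosomes haploid in all males (supports multi-X karyotypes).
    """
    tracks = list(tracks)
    if not any(t.sex == "male" for t in tracks):
        raise ValueError("at least one male track is required to identify the X")
    grid = tracks[0].windows
    for t in tracks[1:]:
        if not t.windows.same_grid(grid):
            raise ValueError("all tracks must share one window grid")
    all_chroms = list(grid.chrom_lengths)

    def x_from(divisor_chroms: Iterable[str]) -> tuple[frozenset[str], list, dict]:
        rows, normed = [], {}
        candidates: set[str] | None = None
        for t in tracks:
            nt = normalize_coverage(t, divisor_chroms)
            normed[t.sample_id] = nt
            medians = _per_chrom_median(nt, nt.N)
            haploid_here = set()
            for chrom, med in medians.items():
                call = thresholds.classify(med)
                rows.append((t.sample_id, t.sex, chrom, med, call))
                if call == "haploid":
                    haploid_here.add(chrom)
            if t.sex == "male":
                candidates = (
                    haploid_here if candidates is None else candidates & haploid_here
                )
        return frozenset(candidates or ()), rows, normed

    # pass 1: divisor over all chromosomes
    provisional, _, _ = x_from(all_chroms)
    # pass 2: divisor excludes the provisional X
    autosomes = [c for c in all_chroms if c not in provisional] or all_chroms
    final_x, rows, normed = x_from(autosomes)
    if not final_x:
        warnings.warn(
            "no chromosome is haploid in all males; X not identified "
            "(male data absent or sexes mislabelled?)"
        )
    calls = pd.DataFrame(
        rows, columns=["sample_id", "sex", "chrom", "median_N", "call"]
    )
    return XInference(final_x, calls, normed)


@dataclass(frozen=True)
class SharedRegion:
    """A maximal merged male-diploid interval on the X."""

    chrom: str
    start: int
    end: int
    n_bins: int
    n_gap_bins_absorbed: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LowCoverageRegion:
    """A run of bins with low coverage in both sexes, excluded from calling."""

    chrom: str
    start: int
    end: int
    n_bins: int


@dataclass(frozen=True)
class SharedRegionParams:
    """Tunable parameters of the shared-region caller.

    ratio_threshold: bins with male/female N below this are female-dominated.
    merge_gap: qualifying bins separated by this many bp or less (inclusive)
        of non-qualifying bins are merged; must be a multiple of bin_size.
    min_region_length: merged intervals shorter than this are discarded.
    low_coverage_N: bins with N below this in BOTH sexes are masked — they
        behave as gaps for merging and long masked runs are reported
        separately (mechanising the manual exclusion of regions with low
        coverage in both sexes).
    """

    ratio_threshold: float = 0.8
    bin_size: int = 100_000
    merge_gap: int = 200_000
    min_region_length: int = 1_000_000
    low_coverage_N: float = 0.25

    def __post_init__(self) -> None:
        for name in ("ratio_threshold", "bin_size", "merge_gap", "min_region_length",
                     "low_coverage_N"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.merge_gap % self.bin_size != 0:
            raise ValueError("merge_gap must be an integer multiple of bin_size")


@dataclass
class RegionCall:
    """Shared regions plus low-coverage exclusions for one X chromosome."""

    regions: list[SharedRegion]
    low_coverage_exclusions: list[LowCoverageRegion]


QUALIFYING, FEMALE_DOMINATED, MASKED = "Q", "F", "M"


def classify_bins(
    n_male: np.ndarray, n_female: np.ndarray, params: SharedRegionParams
) -> np.ndarray:
    """Per-bin classification into qualifying / female-dominated / masked.

    Masking (low coverage in both sexes) takes precedence. A bin with zero
    female coverage but adequate male coverage is *not* female-dominated
    (the ratio is effectively infinite).
    """
    n_male = np.asarray(n_male, dtype=float)
    n_female = np.asarray(n_female, dtype=float)
    classes = np.full(n_male.shape, QUALIFYING, dtype="<U1")
    masked = (n_male < params.low_coverage_N) & (n_female < params.low_coverage_N)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(n_female > 0, n_male / n_female, np.inf)
    classes[ratio < params.ratio_threshold] = FEMALE_DOMINATED
    classes[masked] = MASKED
    return classes


def merge_classified_bins(
    classes: Sequence[str],
    starts: np.ndarray,
    ends: np.ndarray,
    chrom: str,
    params: SharedRegionParams,
) -> RegionCall:
    """Merge qualifying bins across short gaps and apply the length floor.

    Gap span between consecutive qualifying bins is the summed length of
    the intervening non-qualifying bins; 'separated by merge_gap or less'
    is inclusive at exactly merge_gap. Regions are trimmed to start at the
    first and end at the last qualifying bin, and kept when their length
    is at least min_region_length (inclusive).
    """
    classes = np.asarray(classes)
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    lengths = ends - starts
    q_idx = np.flatnonzero(classes == QUALIFYING)
    regions: list[SharedRegion] = []
    if q_idx.size:
        groups: list[list[int]] = [[int(q_idx[0])]]
        for i in q_idx[1:]:
            prev = groups[-1][-1]
            gap_span = int(lengths[prev + 1 : i].sum())
            if gap_span <= params.merge_gap:
                groups[-1].append(int(i))
            else:
                groups.append([int(i)])
        for grp in groups:
            first, last = grp[0], grp[-1]
            start, end = int(starts[first]), int(ends[last])
            if end - start >= params.min_region_length:
                n_bins = last - first + 1
                regions.append(
                    SharedRegion(chrom, start, end, n_bins, n_bins - len(grp))
                )
    # masked runs longer than merge_gap are reported as exclusions
    exclusions: list[LowCoverageRegion] = []
    i = 0
    n = len(classes)
    while i < n:
        if classes[i] == MASKED:
            j = i
            while j + 1 < n and classes[j + 1] == MASKED:
                j += 1
            span = int(ends[j] - starts[i])
            if span > params.merge_gap:
                exclusions.append(
                    LowCoverageRegion(chrom, int(starts[i]), int(ends[j]), j - i + 1)
                )
            i = j + 1
        else:
            i += 1
    return RegionCall(regions, exclusions)


def call_shared_regions(
    male: NormalizedCoverageTrack,
    female: NormalizedCoverageTrack,
    x_chrom: str,
    params: SharedRegionParams = SharedRegionParams(),
) -> RegionCall:
    """Call X-Y shared (male-diploid) regions on one X chromosome.

    Bins of the X are classified from the male and female normalised
    coverage (see :func:`classify_bins`); qualifying (non-female-dominated)
    bins are merged across gaps of at most ``merge_gap`` bp and merged
    intervals of at least ``min_region_length`` bp are returned, along
    with runs of low-coverage bins long enough to have broken a region.
    """
    if not male.windows.same_grid(female.windows):
        raise ValueError("male and female tracks are on different window grids")
    if x_chrom not in male.windows.chrom_lengths:
        raise ValueError(f"unknown X chromosome {x_chrom!r}")
    off = male.windows.offset(x_chrom)
    n = male.windows.n_windows(x_chrom)
    starts, ends = male.windows.bounds(x_chrom)
    n_m = male.N[off : off + n]
    n_f = female.N[off : off + n]
    classes = classify_bins(n_m, n_f, params)
    return merge_classified_bins(classes, starts, ends, x_chrom, params)


def region_length_mb(start: int, end: int) -> float:
    """Region length in Mb, rounded half-up to one decimal (report style)."""
    if end <= start:
        raise ValueError(f"end ({end}) must exceed start ({start})")
    mb = Decimal(end - start) / Decimal(1_000_000)
    return float(mb.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def render_region(chrom: str, start: int, end: int) -> str:
    """Render an internal half-open region 1-based inclusive for reports."""
    return f"{chrom}:{start + 1:,}–{end:,}"
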