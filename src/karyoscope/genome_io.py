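"""Genomic windows and readers/writers for the formats the pipeline touches.

All internal coordinates are 0-based, half-open (BED convention). BUSCO
full tables and VCFs, which are 1-based on disk, are converted on read.
User-facing region strings are rendered 1-based inclusive (see
:func:`karyoscope.sexlink.render_region`).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, TextIO, Union

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "GenomeWindows",
    "Marker",
    "CoverageTrack",
    "HetSnpTable",
    "AlignmentRecord",
    "make_windows",
    "read_busco_markers",
    "read_het_snps",
    "write_het_snps_vcf",
    "read_alignments",
    "read_coverage_bed",
    "write_coverage_bed",
    "read_windows_bed",
    "write_windows_bed",
    "chrom_lengths_from_fasta",
    "read_fasta",
]

PathLike = Union[str, Path]

MARKER_STATUSES = ("complete", "duplicated", "fragmented", "missing")


@dataclass
class GenomeWindows:
    """An ordered, non-overlapping tiling of chromosomes into fixed-size bins.

    Windows per chromosome are sorted, disjoint and tile ``[0, length)``;
    every window has length ``nominal_size`` except possibly the last one
    of each chromosome, which is kept even when short (depth values are
    per-base means, so short windows remain comparable).
    """

    chrom_lengths: dict[str, int]
    nominal_size: int

    def __post_init__(self) -> None:
        if self.nominal_size < 1:
            raise ValueError(f"nominal window size must be >= 1, got {self.nominal_size}")
        for chrom, length in self.chrom_lengths.items():
            if length < 1:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def n_windows(self, chrom: str) -> int:
        length = self.chrom_lengths[chrom]
        return -(-length // self.nominal_size)  # ceil division

    def __len__(self) -> int:
        return sum(self.n_windows(c) for c in self.chrom_lengths)

    def offset(self, chrom: str) -> int:
        """Row index of the first window of *chrom* in the flattened table."""
        off = 0
        for c in self.chrom_lengths:
            if c == chrom:
                return off
            off += self.n_windows(c)
        raise KeyError(chrom)

    def index(self, chrom: str, pos: int) -> int:
        """Flattened index of the window containing 0-based position *pos*."""
        length = self.chrom_lengths.get(chrom)
        if length is None:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < length:
            raise ValueError(f"position {pos} outside {chrom!r} [0, {length})")
        return self.offset(chrom) + pos // self.nominal_size

    def bounds(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays for one chromosome."""
        length = self.chrom_lengths[chrom]
        starts = np.arange(0, length, self.nominal_size, dtype=np.int64)
        ends = np.minimum(starts + self.nominal_size, length)
        return starts, ends

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for chrom in self.chrom_lengths:
            starts, ends = self.bounds(chrom)
            for s, e in zip(starts, ends):
                yield chrom, int(s), int(e)

    def to_frame(self) -> pd.DataFrame:
        rows = list(self)
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def window_lengths(self) -> np.ndarray:
        return (self.to_frame()["end"] - self.to_frame()["start"]).to_numpy()

    def same_grid(self, other: "GenomeWindows") -> bool:
        return (
            self.nominal_size == other.nominal_size
            and self.chrom_lengths == other.chrom_lengths
        )

    def chrom_mask(self, chroms: Iterable[str]) -> np.ndarray:
        """Boolean mask over flattened windows for the given chromosomes."""
        wanted = set(chroms)
        mask = np.zeros(len(self), dtype=bool)
        for chrom in self.chrom_lengths:
            if chrom in wanted:
                off = self.offset(chrom)
                mask[off : off + self.n_windows(chrom)] = True
        return mask


def make_windows(chrom_lengths: Mapping[str, int], nominal_size: int) -> GenomeWindows:
    """Tile each chromosome into non-overlapping windows of *nominal_size* bp.

    The final window of a chromosome may be shorter than *nominal_size*;
    it is always kept.
    """
    return GenomeWindows(dict(chrom_lengths), int(nominal_size))


@dataclass(frozen=True)
class Marker:
    """A placed ortholog (BUSCO) marker in internal 0-based half-open coordinates."""

    marker_id: str
    status: str  # complete | duplicated | fragmented
    chrom: str
    start: int
    end: int


@dataclass
class CoverageTrack:
    """Per-window mean read depth for one sample on a :class:`GenomeWindows` grid."""

    sample_id: str
    sex: str  # male | female | unknown
    windows: GenomeWindows
    depth: np.ndarray

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"invalid sex label {self.sex!r}")
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.shape != (len(self.windows),):
            raise ValueError(
                f"depth has {self.depth.shape[0]} values but grid has "
                f"{len(self.windows)} windows"
            )
        if (self.depth < 0).any():
            raise ValueError("negative depth values")


@dataclass
class HetSnpTable:
    """Heterozygous biallelic SNPs for one sample.

    ``table`` has columns chrom, pos (0-based), ref, alt; one row per
    heterozygous biallelic single-nucleotide substitution.
    """

    sample_id: str
    table: pd.DataFrame

    COLUMNS = ("chrom", "pos", "ref", "alt")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"SNP table missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class AlignmentRecord:
    """One genome-alignment record against a target sequence."""

    query_id: str
    target_id: str
    target_start: int
    target_end: int
    length: int
    identity: float  # percent, 0-100
    one_to_one: bool


def _open_text(source: Union[PathLike, TextIO]) -> tuple[TextIO, bool]:
    if hasattr(source, "read"):
        return source, False  # type: ignore[return-value]
    return open(source, "rt"), True


def read_busco_markers(source: Union[PathLike, TextIO]) -> list[Marker]:
    """Parse a BUSCO "full table" TSV into placed :class:`Marker` records.

    Missing BUSCOs yield no marker; Duplicated BUSCOs yield one marker per
    placement (sharing the id). Coordinates are converted from BUSCO's
    1-based inclusive convention to 0-based half-open.
    """
    handle, close = _open_text(source)
    markers: list[Marker] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed BUSCO row at line {lineno}: {line!r}")
            marker_id, status = fields[0], fields[1].lower()
            if status not in MARKER_STATUSES:
                raise ValueError(
                    f"unknown BUSCO status {fields[1]!r} at line {lineno}"
                )
            if status == "missing":
                continue
            if len(fields) < 5:
                raise ValueError(
                    f"malformed BUSCO row (no coordinates) at line {lineno}: {line!r}"
                )
            chrom = fields[2]
            try:
                a, b = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric coordinates at line {lineno}: {line!r}"
                ) from exc
            start, end = min(a, b) - 1, max(a, b)
            if end <= start:
                raise ValueError(f"empty interval at line {lineno}: {line!r}")
            markers.append(Marker(marker_id, status, chrom, start, end))
    finally:
        if close:
            handle.close()
    return markers


def read_het_snps(vcf_path: PathLike, sample_id: str) -> HetSnpTable:
    """Extract heterozygous biallelic SNPs for one sample from a VCF.

    A record is kept only if it is a single-base substitution with exactly
    one ALT allele, the sample genotype is heterozygous, and the FILTER
    field does not carry the ``RefCall`` label (matched as a whole token,
    case-sensitively — the label emitted by DeepVariant for
    reference-supporting candidate sites).
    """
    vf = pysam.VariantFile(str(vcf_path))
    if sample_id not in vf.header.samples:
        raise ValueError(f"sample {sample_id!r} absent from VCF {vcf_path}")
    rows = []
    for rec in vf:
        if "RefCall" in rec.filter.keys():
            continue
        if rec.ref is None or len(rec.ref) != 1:
            continue
        alts = rec.alts or ()
        if len(alts) != 1 or alts[0] is None or len(alts[0]) != 1:
            continue
        if rec.ref.upper() not in "ACGT" or alts[0].upper() not in "ACGT":
            continue
        gt = rec.samples[sample_id].get("GT")
        if gt is None or len(gt) != 2 or None in gt:
            continue
        if gt[0] == gt[1]:
            continue  # homozygous
        rows.append((rec.chrom, rec.start, rec.ref.upper(), alts[0].upper()))
    vf.close()
    table = pd.DataFrame(rows, columns=list(HetSnpTable.COLUMNS))
    return HetSnpTable(sample_id, table)


def write_het_snps_vcf(
    snps: HetSnpTable, chrom_lengths: Mapping[str, int], path: PathLike
) -> None:
    """Serialize a het-SNP table as a minimal valid VCF (GT 0/1 for all rows)."""
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=karyoscope\n")
        fh.write('##FILTER=<ID=PASS,Description="All filters passed">\n')
        fh.write('##FILTER=<ID=RefCall,Description="Reference call">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{snps.sample_id}\n"
        )
        for row in snps.table.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\t"
                "GT\t0/1\n"
            )


def read_alignments(
    source: Union[PathLike, TextIO],
    min_length: int = 1000,
    require_one_to_one: bool = True,
) -> list[AlignmentRecord]:
    """Read a tabular alignment file and apply the retention filters.

    Expects a TSV with header ``query,target,tstart,tend,length,identity,
    one_to_one``. Records shorter than *min_length* (the 1 kb threshold is
    inclusive: length == min_length is retained) or, when
    *require_one_to_one* is set, not flagged one-to-one, are dropped.
    """
    handle, close = _open_text(source)
    try:
        df = pd.read_csv(handle, sep="\t")
    finally:
        if close:
            handle.close()
    if df.empty:
        return []
    required = {"query", "target", "tstart", "tend", "length", "identity", "one_to_one"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"alignment table missing columns {sorted(missing)}")
    if ((df["identity"] < 0) | (df["identity"] > 100)).any():
        bad = df[(df["identity"] < 0) | (df["identity"] > 100)].iloc[0]
        raise ValueError(f"identity outside [0, 100]: {bad['identity']}")
    records = []
    for row in df.itertuples(index=False):
        one = bool(row.one_to_one)
        length = int(row.length)
        if length <= 0 or int(row.tend) - int(row.tstart) <= 0:
            raise ValueError(f"non-positive alignment length for query {row.query!r}")
        if length < min_length:
            continue
        if require_one_to_one and not one:
            continue
        records.append(
            AlignmentRecord(
                str(row.query), str(row.target), int(row.tstart), int(row.tend),
                length, float(row.identity), one,
            )
        )
    return records


# --- BED I/O -----------------------------------------------------------------

def write_windows_bed(windows: GenomeWindows, path: PathLike) -> None:
    with open(path, "wt") as fh:
        for chrom, start, end in windows:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_windows_bed(path: PathLike) -> GenomeWindows:
    """Reconstruct a window grid from a BED3 tiling.

    The nominal size is taken as the largest window length observed; the
    tiling invariants are re-validated.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end"])
    return _grid_from_frame(df)


def _grid_from_frame(df: pd.DataFrame) -> GenomeWindows:
    if df.empty:
        raise ValueError("empty window BED")
    nominal = int((df["end"] - df["start"]).max())
    chrom_lengths: dict[str, int] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if starts[0] != 0 or (starts[1:] != ends[:-1]).any():
            raise ValueError(f"windows on {chrom!r} do not tile [0, length)")
        chrom_lengths[str(chrom)] = int(ends[-1])
    grid = make_windows(chrom_lengths, nominal)
    if len(grid) != len(df):
        raise ValueError("BED windows are not a fixed-size tiling")
    return grid


def write_coverage_bed(track: CoverageTrack, path: PathLike) -> None:
    """Write a per-window depth track as BED4 (chrom, start, end, mean depth)."""
    with open(path, "wt") as fh:
        for (chrom, start, end), depth in zip(track.windows, track.depth):
            fh.write(f"{chrom}\t{start}\t{end}\t{depth:.6f}\n")


def read_coverage_bed(path: PathLike, sample_id: str, sex: str = "unknown") -> CoverageTrack:
    """Read a BED4 per-window depth track (as produced by e.g. mosdepth)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "depth"]
    )
    grid = _grid_from_frame(df[["chrom", "start", "end"]])
    return CoverageTrack(sample_id, sex, grid, df["depth"].to_numpy(dtype=float))


# --- FASTA helpers -----------------------------------------------------------

def chrom_lengths_from_fasta(path: PathLike) -> dict[str, int]:
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), build_index=True, rebuild=False)
    lengths = {name: len(fa[name]) for name in fa.keys()}
    fa.close()
    return lengths


def read_fasta(path: PathLike) -> dict[str, str]:
    """Load all sequences of a FASTA into memory (case preserved)."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), build_index=True, rebuild=False)
    seqs = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return seqs
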