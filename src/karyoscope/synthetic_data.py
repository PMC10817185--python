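"""Synthetic nematode genomes with known karyotype history and sex signals.

The generator builds chromosomes from the seven ancestral Nigon elements
via an explicit fusion history (with seeded internal inversions to model
post-fusion intermixing), then emits everything the analysis consumes:

* a FASTA genome with telomere-repeat arrays at chromosome ends,
* a BUSCO-like marker table plus the matching marker->element map,
* sexed per-window coverage tracks with ploidy-aware negative-binomial
  depth (haploid male X; male-diploid neo-Y shared region; optional
  embryo-driven dilution of female X coverage),
* a male heterozygous-SNP VCF whose density is elevated inside the shared
  region and in the bin bordering it,
* a truth file recording the planted karyotype, X, shared region, strata
  and rates for parameter-recovery tests.

Four presets mirror the chromosome architectures of the filarial species
the analysis targets (an X0 species with an X+D fused X, and three XY
species whose neo-Y shared regions sit in the ancestrally autosomal
partition of the X).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_io import (
    CoverageTrack,
    GenomeWindows,
    HetSnpTable,
    Marker,
    PathLike,
    make_windows,
    write_coverage_bed,
    write_het_snps_vcf,
)
from .nigon_paint import NIGON_ELEMENTS
from .seqfeatures import NEMATODE_TELOMERE

import pandas as pd

__all__ = [
    "ElementSpec",
    "FusionEvent",
    "SimulationConfig",
    "TruthSet",
    "preset",
    "PRESETS",
    "build_karyotype",
    "simulate_markers",
    "simulate_coverage",
    "simulate_snps",
    "simulate_sequences",
    "write_fixture_set",
]

# rng stream ids, so the per-output substreams are independent of one another
_STREAM_KARYOTYPE = 1
_STREAM_MARKERS = 2
_STREAM_COV_MALE = 3
_STREAM_COV_FEMALE = 4
_STREAM_SNPS = 5
_STREAM_SEQ = 6


@dataclass(frozen=True)
class ElementSpec:
    """Size of one ancestral element: bp of sequence and number of markers."""

    bp: int
    n_markers: int


@dataclass(frozen=True)
class FusionEvent:
    """Fuse the chromosome carrying *left* to the one carrying *right*.

    ``inversions`` random internal inversions are applied to the fused
    chromosome immediately after the event, before any later fusion —
    older fusions therefore end up more intermixed than recent ones, as
    in real karyotype histories.
    """

    left: str
    right: str
    orientation: str = "forward"  # or "inverted": right partner is flipped
    inversions: int = 0


@dataclass
class SimulationConfig:
    """Full description of one simulated study system.

    depth_mean is the per-base read depth of a diploid region;
    depth_dispersion is the negative-binomial size parameter (per-window
    depth has CV ~ 1/sqrt(dispersion); the Poisson limit is dispersion ->
    infinity). embryo_fraction e is the fraction of female-derived DNA
    contributed by in-utero embryos (1:1 sex ratio), giving an expected
    female X:autosome coverage ratio of 1 - e/4. The neo-Y geometry is a
    shared (male-diploid) interval on the X in X-chromosome coordinates,
    minus optional haploid degeneration strata inside it.
    """

    elements: dict[str, ElementSpec]
    fusion_history: list[FusionEvent] = field(default_factory=list)
    depth_mean: float = 30.0
    depth_dispersion: float = 100.0
    embryo_fraction: float = 0.0
    shared_region: tuple[int, int] | None = None
    degeneration_strata: list[tuple[int, int]] = field(default_factory=list)
    snp_rate_shared: float = 0.0
    snp_rate_boundary_multiplier: float = 7.0
    telomere_repeats_per_end: int = 50
    bin_size: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.elements) - set(NIGON_ELEMENTS)
        if unknown:
            raise ValueError(f"unknown elements {sorted(unknown)}")
        if not 0.0 <= self.embryo_fraction <= 1.0:
            raise ValueError("embryo_fraction must lie in [0, 1]")
        if self.snp_rate_shared < 0:
            raise ValueError("snp_rate_shared must be >= 0")
        if self.snp_rate_shared * self.snp_rate_boundary_multiplier > 1:
            raise ValueError("SNP rate exceeds 1 SNP per bp")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


@dataclass
class TruthSet:
    """Ground truth of a simulated genome, for parameter-recovery tests."""

    karyotype: dict[str, list[tuple[str, int]]]  # chrom -> ordered (element, bp)
    x_chrom: str | None
    shared_region: tuple[int, int] | None
    degeneration_strata: list[tuple[int, int]]
    snp_rate_shared: float
    embryo_fraction: float

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: sum(l for _, l in blocks) for c, blocks in self.karyotype.items()}

    def partitions(self, chrom: str) -> list[tuple[str, int, int]]:
        """Maximal same-element intervals of one chromosome, in order."""
        out: list[tuple[str, int, int]] = []
        pos = 0
        for element, length in self.karyotype[chrom]:
            if out and out[-1][0] == element:
                prev = out.pop()
                out.append((element, prev[1], pos + length))
            else:
                out.append((element, pos, pos + length))
            pos += length
        return out

    def element_territory(self, chrom: str, element: str) -> list[tuple[int, int]]:
        return [(s, e) for el, s, e in self.partitions(chrom) if el == element]

    def fused_components(self) -> dict[str, frozenset[str]]:
        return {
            c: frozenset(el for el, _ in blocks)
            for c, blocks in self.karyotype.items()
        }

    def male_diploid_intervals(self) -> list[tuple[int, int]]:
        """Shared region minus degeneration strata, as X-coordinate intervals."""
        if self.shared_region is None:
            return []
        s0, e0 = self.shared_region
        cuts = sorted((max(s0, s), min(e0, e)) for s, e in self.degeneration_strata)
        out, pos = [], s0
        for s, e in cuts:
            if s > pos:
                out.append((pos, s))
            pos = max(pos, e)
        if pos < e0:
            out.append((pos, e0))
        return out

    def male_x_ploidy(self, start: int, end: int) -> float:
        """Mean male copy number of the X interval [start, end)."""
        diploid = sum(
            max(0, min(end, e) - max(start, s))
            for s, e in self.male_diploid_intervals()
        )
        return 1.0 + diploid / (end - start)

    def to_json(self) -> str:
        payload = {
            "karyotype": {c: [[el, l] for el, l in b] for c, b in self.karyotype.items()},
            "chrom_lengths": self.chrom_lengths,
            "x_chrom": self.x_chrom,
            "shared_region": list(self.shared_region) if self.shared_region else None,
            "degeneration_strata": [list(s) for s in self.degeneration_strata],
            "snp_rate_shared": self.snp_rate_shared,
            "embryo_fraction": self.embryo_fraction,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        d = json.loads(text)
        return cls(
            karyotype={c: [(el, l) for el, l in b] for c, b in d["karyotype"].items()},
            x_chrom=d["x_chrom"],
            shared_region=tuple(d["shared_region"]) if d["shared_region"] else None,
            degeneration_strata=[tuple(s) for s in d["degeneration_strata"]],
            snp_rate_shared=d["snp_rate_shared"],
            embryo_fraction=d["embryo_fraction"],
        )


# --- karyotype construction --------------------------------------------------

def _split_blocks(
    blocks: list[tuple[str, int]], cut: int
) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    left: list[tuple[str, int]] = []
    pos = 0
    for i, (el, length) in enumerate(blocks):
        if pos + length <= cut:
            left.append((el, length))
            pos += length
            continue
        if cut > pos:
            left.append((el, cut - pos))
        right = ([(el, pos + length - cut)] if pos + length > cut else [])
        return left, right + blocks[i + 1 :]
    return left, []


def _coalesce(blocks: Iterable[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for el, length in blocks:
        if length == 0:
            continue
        if out and out[-1][0] == el:
            out[-1] = (el, out[-1][1] + length)
        else:
            out.append((el, length))
    return out


def _invert(blocks: list[tuple[str, int]], a: int, b: int) -> list[tuple[str, int]]:
    left, rest = _split_blocks(blocks, a)
    mid, right = _split_blocks(rest, b - a)
    return _coalesce(left + mid[::-1] + right)


def build_karyotype(config: SimulationConfig) -> TruthSet:
    """Apply the fusion history to the seven elements and plant the neo-Y.

    Each fusion joins the two chromosomes currently carrying the named
    elements (joining two elements already on one chromosome is an error)
    and then applies that event's seeded random internal inversions to
    the fused product. The planted shared region must fall entirely
    within a single non-X-element partition of the X chromosome — the
    neo-Y, being the unfused homologue of a fused autosome, can only
    share ancestrally autosomal sequence with the X.
    """
    rng = config.rng(_STREAM_KARYOTYPE)
    units: list[list[tuple[str, int]]] = [
        [(el, spec.bp)] for el, spec in config.elements.items()
    ]

    def unit_of(element: str) -> int:
        for i, u in enumerate(units):
            if any(el == element for el, _ in u):
                return i
        raise ValueError(f"element {element!r} not in karyotype")

    for ev in config.fusion_history:
        i, j = unit_of(ev.left), unit_of(ev.right)
        if i == j:
            raise ValueError(
                f"elements {ev.left!r} and {ev.right!r} are already on one chromosome"
            )
        right = units[j]
        if ev.orientation == "inverted":
            right = right[::-1]
        elif ev.orientation != "forward":
            raise ValueError(f"unknown orientation {ev.orientation!r}")
        fused = _coalesce(units[i] + right)
        total = sum(l for _, l in fused)
        for _ in range(ev.inversions):
            a, b = sorted(rng.integers(0, total + 1, size=2))
            if a < b:
                fused = _invert(fused, int(a), int(b))
        units = [u for k, u in enumerate(units) if k not in (i, j)] + [fused]

    x_unit = None
    autosomal_units = []
    for u in units:
        if any(el == "X" for el, _ in u):
            x_unit = u
        else:
            autosomal_units.append(u)
    autosomal_units.sort(key=lambda u: -sum(l for _, l in u))
    karyotype = {f"chr{k + 1}": u for k, u in enumerate(autosomal_units)}
    x_name = None
    if x_unit is not None:
        x_name = "chrX"
        karyotype[x_name] = x_unit

    truth = TruthSet(
        karyotype=karyotype,
        x_chrom=x_name,
        shared_region=config.shared_region,
        degeneration_strata=list(config.degeneration_strata),
        snp_rate_shared=config.snp_rate_shared,
        embryo_fraction=config.embryo_fraction,
    )
    if config.shared_region is not None:
        if x_name is None:
            raise ValueError("shared region planted but no X chromosome exists")
        s, e = config.shared_region
        x_len = truth.chrom_lengths[x_name]
        if not 0 <= s < e <= x_len:
            raise ValueError(f"shared region ({s}, {e}) outside X [0, {x_len})")
        hosts = {
            el
            for el, ps, pe in truth.partitions(x_name)
            if max(s, ps) < min(e, pe)
        }
        if hosts == {"X"} or len(hosts) != 1:
            raise ValueError(
                "shared region must lie within a single ancestrally "
                f"autosomal partition of the X (overlaps {sorted(hosts)})"
            )
    return truth


# --- markers -----------------------------------------------------------------

_MARKER_LEN = 200


def simulate_markers(
    truth: TruthSet, config: SimulationConfig
) -> tuple[list[Marker], dict[str, str]]:
    """Place markers uniformly within each element's territory.

    Every element contributes its configured number of single-copy
    markers; the returned map records each marker's true element, playing
    the role of the external marker->element assignment table.
    """
    rng = config.rng(_STREAM_MARKERS)
    markers: list[Marker] = []
    nigon_map: dict[str, str] = {}
    for ei, el in enumerate(NIGON_ELEMENTS):
        spec = config.elements.get(el)
        if spec is None or spec.n_markers == 0:
            continue
        territory: list[tuple[str, int, int]] = []
        for chrom in truth.karyotype:
            for s, e in truth.element_territory(chrom, el):
                territory.append((chrom, s, e))
        if not territory:
            raise ValueError(f"element {el!r} has no territory")
        sizes = np.array([e - s for _, s, e in territory], dtype=float)
        if spec.n_markers * _MARKER_LEN > sizes.sum():
            raise ValueError(f"marker count for {el!r} exceeds bp capacity")
        blocks = rng.choice(len(territory), size=spec.n_markers, p=sizes / sizes.sum())
        for k in range(spec.n_markers):
            chrom, s, e = territory[int(blocks[k])]
            start = int(rng.integers(s, max(s + 1, e - _MARKER_LEN)))
            end = min(start + _MARKER_LEN, e)
            mid = f"{(ei + 1) * 100000 + k}at6231"
            markers.append(Marker(mid, "complete", chrom, start, end))
            nigon_map[mid] = el
    markers.sort(key=lambda m: (m.chrom, m.start, m.marker_id))
    return markers, nigon_map


# --- coverage ----------------------------------------------------------------

def _window_mean_depth(
    truth: TruthSet, sex: str, config: SimulationConfig, windows: GenomeWindows
) -> np.ndarray:
    means = np.zeros(len(windows), dtype=float)
    e = config.embryo_fraction
    for i, (chrom, start, end) in enumerate(windows):
        if chrom != truth.x_chrom:
            means[i] = config.depth_mean  # diploid autosome in both sexes
        elif sex == "female":
            # adult XX plus 1:1 male/female embryos at DNA fraction e
            means[i] = config.depth_mean * (1 - e / 4)
        else:
            means[i] = config.depth_mean * truth.male_x_ploidy(start, end) / 2
    return means


def simulate_coverage(
    truth: TruthSet, sex: str, config: SimulationConfig, sample_id: str | None = None
) -> CoverageTrack:
    """Draw a per-window depth track for one sexed sample.

    Per-window depth is a negative-binomial draw of the window's total
    aligned bases (mean = per-base mean x window length, dispersion =
    ``depth_dispersion``) divided by window length. Males are haploid on
    the X except inside the shared region net of degeneration strata;
    females are diploid on the X but diluted by embryo DNA.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"invalid sex label {sex!r}")
    rng = config.rng(_STREAM_COV_MALE if sex == "male" else _STREAM_COV_FEMALE)
    windows = make_windows(truth.chrom_lengths, config.bin_size)
    means = _window_mean_depth(truth, sex, config, windows)
    lengths = np.array([e - s for _, s, e in windows], dtype=float)
    m = means * lengths  # expected bases per window
    r = config.depth_dispersion
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(m > 0, r / (r + m), 1.0)
    bases = rng.negative_binomial(r, p)
    return CoverageTrack(
        sample_id or f"sim_{sex}", sex, windows, bases / lengths
    )


# --- SNPs --------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_snps(
    truth: TruthSet, config: SimulationConfig, sample_id: str = "sim_male"
) -> HetSnpTable:
    """Draw male heterozygous SNPs over the planted X-Y shared region.

    SNP counts are Poisson at rate ``snp_rate_shared`` per bp across the
    male-diploid span (shared region minus strata), boosted by
    ``snp_rate_boundary_multiplier`` in the single bin bordering the
    region's proximal edge (gametolog divergence bleeding across the
    recombination-arrest boundary), and zero elsewhere.
    """
    rng = config.rng(_STREAM_SNPS)
    rows: list[tuple[str, int, str, str]] = []
    if truth.shared_region is not None and truth.snp_rate_shared > 0:
        x = truth.x_chrom
        assert x is not None
        spans = [
            (s, e, truth.snp_rate_shared) for s, e in truth.male_diploid_intervals()
        ]
        s0 = truth.shared_region[0]
        b_start = max(0, s0 - config.bin_size)
        if b_start < s0:
            spans.append(
                (b_start, s0,
                 truth.snp_rate_shared * config.snp_rate_boundary_multiplier)
            )
        for s, e, rate in sorted(spans):
            n = rng.poisson(rate * (e - s))
            if n == 0:
                continue
            pos = np.unique(rng.integers(s, e, size=n))
            refs = rng.integers(0, 4, size=pos.size)
            alts = (refs + rng.integers(1, 4, size=pos.size)) % 4
            for p_, rf, al in zip(pos, refs, alts):
                rows.append((x, int(p_), str(_BASES[rf]), str(_BASES[al])))
    table = pd.DataFrame(rows, columns=list(HetSnpTable.COLUMNS))
    return HetSnpTable(sample_id, table)


# --- sequence ----------------------------------------------------------------

def simulate_sequences(truth: TruthSet, config: SimulationConfig) -> dict[str, str]:
    """Random ACGT chromosome sequences with telomere arrays at both ends.

    The telomere repeat (TTAGGC pointing outward: its reverse complement
    at the left end) overwrites the first and last bases, so sequence
    length equals the karyotype block sum exactly.
    """
    rng = config.rng(_STREAM_SEQ)
    rc = NEMATODE_TELOMERE[::-1].translate(str.maketrans("ACGT", "TGCA"))
    seqs: dict[str, str] = {}
    for chrom, length in truth.chrom_lengths.items():
        arr = rng.integers(0, 4, size=length)
        seq = "".join(_BASES[arr]) if length < 1 << 20 else _fast_bases(arr)
        telo = NEMATODE_TELOMERE * config.telomere_repeats_per_end
        left = (rc * config.telomere_repeats_per_end)[: length // 2]
        right = telo[: length - len(left)] if len(telo) > length - len(left) else telo
        seq = left + seq[len(left) : length - len(right)] + right
        seqs[chrom] = seq
    return seqs


def _fast_bases(arr: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[arr].tobytes().decode("ascii")


# --- presets -----------------------------------------------------------------

# Markers per element in the presets. The marker set subsamples a
# conserved-ortholog catalogue at ~500 kb spacing: sparse enough that a
# ~200-inversion fusion history randomizes marker order at marker
# resolution (element runs after K inversions cannot be shorter than
# ~chromosome/2K, so markers spaced below that scale would stay locally
# correlated however old the fusion), yet several-fold above the fusion
# caller's minimum marker count.
_N_MARKERS = 20


def _mk(bp_by_element: Mapping[str, int]) -> dict[str, ElementSpec]:
    return {el: ElementSpec(bp, _N_MARKERS) for el, bp in bp_by_element.items()}


def preset(name: str, seed: int = 0) -> SimulationConfig:
    """A named study-system architecture with its planted signals.

    ``litomosoides``: ancestral 5A+X karyotype (X = intermixed X+D
    fusion), X0 males, embryo-diluted females, no neo-Y.
    ``dirofilaria``: 4A+XY; the whole E partition of the X is shared with
    an essentially undegenerated neo-Y.
    ``onchocerca``: 3A+XY (extra A+N autosome fusion); only the distal
    3.4 Mb of the E partition remains shared, with high divergence.
    ``brugia``: 4A+XY via an independent X+N fusion; a 2.6 Mb shared
    region at the distal end of the N partition.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], seed=seed)


PRESETS: dict[str, SimulationConfig] = {
    # X0, X = X+D, chromosome sizes sum to 65.9 Mb with N50 10.9 Mb
    "litomosoides": SimulationConfig(
        elements=_mk(
            {"A": 11_700_000, "B": 11_300_000, "C": 10_900_000,
             "E": 10_600_000, "N": 10_500_000, "X": 5_900_000, "D": 5_000_000}
        ),
        fusion_history=[FusionEvent("X", "D", inversions=200)],
        embryo_fraction=0.8,
    ),
    # 4A + XY; shared region = entire E partition of the 28.2 Mb X
    "dirofilaria": SimulationConfig(
        elements=_mk(
            {"A": 15_600_000, "B": 15_000_000, "C": 14_500_000,
             "N": 14_000_000, "X": 6_500_000, "D": 6_500_000, "E": 15_232_375}
        ),
        fusion_history=[
            FusionEvent("X", "D", inversions=200),
            FusionEvent("X", "E", inversions=0),
        ],
        shared_region=(13_000_000, 28_232_375),
        snp_rate_shared=1 / 2215,
    ),
    # 3A + XY; only the distal 3.4 Mb of the E partition is still shared
    "onchocerca": SimulationConfig(
        elements=_mk(
            {"B": 15_000_000, "C": 13_000_000, "A": 13_600_000,
             "N": 11_400_000, "X": 7_000_000, "D": 6_500_000, "E": 11_985_961}
        ),
        fusion_history=[
            FusionEvent("X", "D", inversions=200),
            FusionEvent("X", "E", inversions=0),
            FusionEvent("A", "N", inversions=150),
        ],
        shared_region=(22_100_000, 25_485_961),
        snp_rate_shared=1 / 314,
    ),
    # 4A + XY via X+N; 2.6 Mb shared region at the distal end of NigonN
    "brugia": SimulationConfig(
        elements=_mk(
            {"C": 14_700_000, "A": 14_200_000, "E": 13_900_000,
             "B": 13_400_000, "X": 7_700_000, "D": 7_000_000, "N": 10_243_668}
        ),
        fusion_history=[
            FusionEvent("X", "D", inversions=200),
            FusionEvent("X", "N", inversions=0),
        ],
        shared_region=(22_300_000, 24_943_668),
        snp_rate_shared=1 / 2215,
    ),
}


# --- fixture emission --------------------------------------------------------

def write_fixture_set(
    config: SimulationConfig, outdir: PathLike, write_genome: bool = True
) -> dict[str, str]:
    """Emit a complete fixture directory; returns filename -> SHA-256.

    Re-running with the same config and seed reproduces byte-identical
    files. ``write_genome=False`` skips the (large) FASTA when only
    tables and tracks are needed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = build_karyotype(config)
    markers, nigon_map = simulate_markers(truth, config)

    paths: list[Path] = []

    busco = outdir / "busco_full_table.tsv"
    with open(busco, "wt") as fh:
        fh.write("# BUSCO-style full table (synthetic)\n")
        fh.write("# Busco id\tStatus\tSequence\tGene Start\tGene End\tStrand\tScore\tLength\n")
        for m in markers:
            fh.write(
                f"{m.marker_id}\tComplete\t{m.chrom}\t{m.start + 1}\t{m.end}\t+\t"
                f"100.0\t{m.end - m.start}\n"
            )
    paths.append(busco)

    nmap = outdir / "nigon_map.tsv"
    with open(nmap, "wt") as fh:
        fh.write("busco_id\tnigon\n")
        for mid in sorted(nigon_map):
            fh.write(f"{mid}\t{nigon_map[mid]}\n")
    paths.append(nmap)

    for sex in ("male", "female"):
        track = simulate_coverage(truth, sex, config)
        p = outdir / f"cov_{sex}.bed"
        write_coverage_bed(track, p)
        paths.append(p)

    snps = simulate_snps(truth, config)
    vcf = outdir / "snps_male.vcf"
    write_het_snps_vcf(snps, truth.chrom_lengths, vcf)
    paths.append(vcf)

    truth_path = outdir / "truth.json"
    truth_path.write_text(truth.to_json() + "\n")
    paths.append(truth_path)

    if write_genome:
        fasta = outdir / "genome.fa"
        with open(fasta, "wt") as fh:
            for chrom, seq in simulate_sequences(truth, config).items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        paths.append(fasta)

    manifest = {}
    for p in paths:
        h = hashlib.sha256()
        h.update(p.read_bytes())
        manifest[p.name] = h.hexdigest()
    return manifest
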