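"""Sequence-feature tracks: telomere repeats, repeat density, assembly metrics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Seq import reverse_complement

__all__ = [
    "TelomereTrack",
    "AssemblyMetrics",
    "NEMATODE_TELOMERE",
    "telomere_counts",
    "ends_capped",
    "repeat_density",
    "assembly_metrics",
]

NEMATODE_TELOMERE = "TTAGGC"


@dataclass
class TelomereTrack:
    """Telomere-motif occurrences along one sequence.

    Counts are per fixed-size window; ``positions`` holds the start of
    every counted occurrence (either strand) for exact end-of-chromosome
    queries.
    """

    seq_length: int
    motif: str
    window_size: int
    counts: np.ndarray
    positions: np.ndarray


def _find_nonoverlapping(seq: str, motif: str) -> list[int]:
    hits, i = [], seq.find(motif)
    while i != -1:
        hits.append(i)
        i = seq.find(motif, i + len(motif))
    return hits


def telomere_counts(
    seq: str, motif: str = NEMATODE_TELOMERE, window_size: int = 1000
) -> TelomereTrack:
    """Count telomere-motif occurrences in fixed windows along a sequence.

    Occurrences of the motif and of its reverse complement are counted
    (non-overlapping, greedy left-to-right, case-insensitive) so that
    telomere arrays are found regardless of assembly strand; each
    occurrence is assigned to the window containing its start.
    """
    if not motif:
        raise ValueError("empty telomere motif")
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif must be plain ACGT, got {motif!r}")
    up = seq.upper()
    positions = _find_nonoverlapping(up, motif)
    rc = reverse_complement(motif)
    if rc != motif:
        positions = positions + _find_nonoverlapping(up, rc)
    positions = np.array(sorted(positions), dtype=np.int64)
    n_windows = max(1, -(-len(seq) // window_size))
    counts = np.zeros(n_windows, dtype=np.int64)
    if positions.size:
        np.add.at(counts, positions // window_size, 1)
    return TelomereTrack(len(seq), motif, window_size, counts, positions)


def ends_capped(
    track: TelomereTrack, end_span: int = 10_000, min_count: int = 10
) -> tuple[bool, bool]:
    """Is each chromosome end capped by a telomere-repeat array?

    An end is capped when at least *min_count* motif occurrences start
    within *end_span* bp of it.
    """
    if end_span > track.seq_length:
        warnings.warn(
            f"end_span {end_span} exceeds sequence length {track.seq_length}; "
            "evaluating over the full sequence"
        )
        end_span = track.seq_length
    left = int((track.positions < end_span).sum())
    right = int((track.positions >= track.seq_length - end_span).sum())
    return left >= min_count, right >= min_count


def repeat_density(seq: str, window_size: int = 200_000) -> np.ndarray:
    """Fraction of softmasked (lowercase) bases per non-overlapping window.

    Works on any softmasked FASTA sequence regardless of which repeat
    finder produced the mask; note that different finders can mask very
    different genome fractions.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lower = ((arr >= 97) & (arr <= 122)).astype(np.int64)
    n_windows = max(1, -(-len(seq) // window_size))
    edges = np.arange(0, n_windows) * window_size
    sums = np.add.reduceat(lower, edges) if len(seq) else np.zeros(n_windows)
    lengths = np.minimum(edges + window_size, len(seq)) - edges
    return sums / lengths


@dataclass(frozen=True)
class AssemblyMetrics:
    """Assembly summary: span, sequence count, N50 and base accuracy."""

    span: int
    n_sequences: int
    n50: int
    qv: float | None = None
    error_spacing_bp: float | None = None  # one error every this many bp


def assembly_metrics(
    lengths: Sequence[int], qv: float | None = None
) -> AssemblyMetrics:
    """Span, sequence count and N50, plus QV -> error-spacing conversion.

    N50 is the length of the shortest sequence in the smallest
    descending-sorted prefix whose sum reaches half the span. A Phred
    consensus quality QV implies one error every 10^(QV/10) bp.
    """
    if not lengths:
        raise ValueError("no sequence lengths given")
    if any(l <= 0 for l in lengths):
        raise ValueError("sequence lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    span = sum(ordered)
    acc, n50 = 0, ordered[0]
    for l in ordered:
        acc += l
        if acc >= span / 2:
            n50 = l
            break
    spacing = 10 ** (qv / 10) if qv is not None else None
    return AssemblyMetrics(span, len(ordered), n50, qv, spacing)
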