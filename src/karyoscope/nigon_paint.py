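"""Nigon-element chromosome painting.

Extant rhabditid nematode chromosomes are combinations of seven ancestral
linkage groups, the Nigon elements (A, B, C, D, E, N, X). Painting assigns
each conserved single-copy ortholog (BUSCO) on an assembly to its ancestral
element via a marker->element lookup table, tallies assignments in genomic
windows, detects fused chromosomes (those composed of two or more
elements), and quantifies how intermixed the partitions of a fusion are
with a Wald-Wolfowitz runs statistic.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO, Union

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GenomeWindows, Marker, PathLike, _open_text

__all__ = [
    "NIGON_ELEMENTS",
    "UNASSIGNED",
    "PaintedMarker",
    "ChromosomePaint",
    "IntermixingResult",
    "read_nigon_map",
    "assign_nigon",
    "window_paint",
    "detect_fusions",
    "intermixing_runs",
    "ordered_element_labels",
    "synteny_pairs",
]

NIGON_ELEMENTS = ("A", "B", "C", "D", "E", "N", "X")
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class PaintedMarker:
    marker: Marker
    element: str  # one of NIGON_ELEMENTS or UNASSIGNED


def read_nigon_map(source: Union[PathLike, TextIO]) -> dict[str, str]:
    """Read a marker->Nigon-element table (TSV with header busco_id, nigon)."""
    handle, close = _open_text(source)
    try:
        df = pd.read_csv(handle, sep="\t")
    finally:
        if close:
            handle.close()
    if not {"busco_id", "nigon"} <= set(df.columns):
        raise ValueError("Nigon map must have columns busco_id, nigon")
    bad = set(df["nigon"]) - set(NIGON_ELEMENTS)
    if bad:
        raise ValueError(f"unknown Nigon elements in map: {sorted(bad)}")
    if df["busco_id"].duplicated().any():
        dup = df.loc[df["busco_id"].duplicated(), "busco_id"].iloc[0]
        raise ValueError(f"marker {dup!r} mapped to more than one element")
    return dict(zip(df["busco_id"].astype(str), df["nigon"]))


def assign_nigon(
    markers: Sequence[Marker], nigon_map: Mapping[str, str]
) -> list[PaintedMarker]:
    """Label each placed marker with its ancestral element.

    Markers absent from the map are labelled ``unassigned`` (not an error);
    input order is preserved and duplicated markers each receive the label.
    """
    return [
        PaintedMarker(m, nigon_map.get(m.marker_id, UNASSIGNED)) for m in markers
    ]


@dataclass
class ChromosomePaint:
    """Windowed and per-chromosome tallies of painted markers.

    ``window_counts`` has one row per window of ``windows`` (flattened
    order) and one column per element plus ``unassigned``; a marker is
    counted in the window containing its start coordinate.
    ``composition`` is indexed by chromosome with the same columns.
    """

    windows: GenomeWindows
    window_counts: pd.DataFrame
    composition: pd.DataFrame
    n_skipped: int = 0

    @property
    def fractions(self) -> pd.DataFrame:
        """Per-chromosome element fractions over assigned markers."""
        assigned = self.composition[list(NIGON_ELEMENTS)]
        totals = assigned.sum(axis=1)
        return assigned.div(totals.replace(0, np.nan), axis=0)

    @property
    def dominant(self) -> pd.Series:
        return self.composition[list(NIGON_ELEMENTS)].idxmax(axis=1)


def window_paint(
    painted: Sequence[PaintedMarker],
    windows: GenomeWindows,
    statuses: Iterable[str] = ("complete", "duplicated"),
) -> ChromosomePaint:
    """Tally painted markers per window and per chromosome.

    Fragmented markers are excluded by default (configurable via
    *statuses*); duplicated ones count each placement with weight 1.
    Markers on chromosomes absent from the grid are skipped with a warning.
    """
    allowed = set(statuses)
    cols = list(NIGON_ELEMENTS) + [UNASSIGNED]
    counts = np.zeros((len(windows), len(cols)), dtype=np.int64)
    col_idx = {c: i for i, c in enumerate(cols)}
    skipped = 0
    for pm in painted:
        m = pm.marker
        if m.status not in allowed:
            continue
        if m.chrom not in windows.chrom_lengths:
            skipped += 1
            continue
        counts[windows.index(m.chrom, m.start), col_idx[pm.element]] += 1
    if skipped:
        warnings.warn(f"skipped {skipped} markers on chromosomes absent from grid")
    frame = windows.to_frame()
    window_counts = pd.concat(
        [frame, pd.DataFrame(counts, columns=cols)], axis=1
    )
    composition = window_counts.groupby("chrom", sort=False)[cols].sum()
    return ChromosomePaint(windows, window_counts, composition, skipped)


def detect_fusions(
    paint: ChromosomePaint,
    min_fraction: float = 0.05,
    min_count: int = 10,
) -> dict[str, frozenset[str]]:
    """Identify the ancestral components of each chromosome.

    An element is a component of a chromosome when it contributes at least
    *min_fraction* of the assigned markers AND at least *min_count*
    markers; chromosomes with two or more components are fusions. The
    defaults tolerate isolated mis-assigned markers without spurious
    fusion calls.
    """
    components: dict[str, frozenset[str]] = {}
    for chrom, row in paint.composition.iterrows():
        assigned = row[list(NIGON_ELEMENTS)]
        total = assigned.sum()
        if total == 0:
            raise ValueError(f"unpaintable chromosome: {chrom!r} has no assigned markers")
        keep = assigned[(assigned / total >= min_fraction) & (assigned >= min_count)]
        components[str(chrom)] = frozenset(keep.index)
    return components


@dataclass(frozen=True)
class IntermixingResult:
    """Wald-Wolfowitz runs summary for a two-element fused chromosome.

    A strongly negative z (fewer runs than expected under random
    interleaving) indicates the two partitions remain distinct; z near 0
    indicates they are intermixed.
    """

    elements: tuple[str, str]
    n1: int
    n2: int
    runs: int
    expected_runs: float
    z_score: float
    p_value: float

    @property
    def verdict(self) -> str:
        if self.z_score <= -1.96:
            return "partitioned"
        if abs(self.z_score) < 1.96:
            return "intermixed"
        return "alternating"


def intermixing_runs(labels: Sequence[str]) -> IntermixingResult:
    """Runs test on an ordered sequence of element labels from one chromosome.

    Labels must contain exactly two distinct elements and be ordered by
    marker start position (ties broken by marker id). With n1 and n2
    labels of each kind, the expected run count under random ordering is
    ``1 + 2 n1 n2 / (n1 + n2)`` and the z-score uses the exact runs-test
    variance.
    """
    labels = list(labels)
    distinct = sorted(set(labels))
    if len(distinct) < 2:
        raise ValueError("runs undefined: only one element present")
    if len(distinct) > 2:
        raise ValueError(f"runs test needs exactly two elements, got {distinct}")
    e1, e2 = distinct
    n1 = labels.count(e1)
    n2 = labels.count(e2)
    runs = 1 + sum(a != b for a, b in zip(labels, labels[1:]))
    n = n1 + n2
    expected = 1 + 2 * n1 * n2 / n
    if n < 2 or (n - 1) == 0:
        raise ValueError("runs undefined for fewer than two markers")
    var = 2 * n1 * n2 * (2 * n1 * n2 - n1 - n2) / (n**2 * (n - 1))
    if var <= 0:
        # only possible when n1 = n2 = 1: runs is deterministically 2,
        # which equals its expectation
        z, p = 0.0, 1.0
    else:
        z = (runs - expected) / math.sqrt(var)
        p = 2 * stats.norm.sf(abs(z))
    return IntermixingResult((e1, e2), n1, n2, runs, expected, z, p)


def ordered_element_labels(
    painted: Sequence[PaintedMarker],
    chrom: str,
    elements: tuple[str, str] | None = None,
) -> list[str]:
    """Element labels of assigned markers on *chrom*, ordered by start then id.

    When *elements* is given, labels are restricted to that pair; otherwise
    all assigned labels are returned (intermixing_runs will then require
    exactly two distinct elements).
    """
    on_chrom = [
        pm
        for pm in painted
        if pm.marker.chrom == chrom and pm.element != UNASSIGNED
        and (elements is None or pm.element in elements)
    ]
    on_chrom.sort(key=lambda pm: (pm.marker.start, pm.marker.marker_id))
    return [pm.element for pm in on_chrom]


def synteny_pairs(
    painted_a: Sequence[PaintedMarker], painted_b: Sequence[PaintedMarker]
) -> pd.DataFrame:
    """Positions of markers complete and single-copy in two genomes.

    Returns one row per marker that is complete (not duplicated or
    fragmented) and placed exactly once in both genomes, with columns
    marker_id, chrom_a, pos_a, chrom_b, pos_b, element. Both marker sets
    must have been painted with the same Nigon map, so the element label
    is shared.
    """

    def singles(painted: Sequence[PaintedMarker]) -> dict[str, PaintedMarker]:
        seen: dict[str, list[PaintedMarker]] = {}
        for pm in painted:
            seen.setdefault(pm.marker.marker_id, []).append(pm)
        return {
            mid: pms[0]
            for mid, pms in seen.items()
            if len(pms) == 1 and pms[0].marker.status == "complete"
        }

    a, b = singles(painted_a), singles(painted_b)
    rows = []
    for mid in sorted(set(a) & set(b)):
        pa, pb = a[mid], b[mid]
        rows.append(
            (mid, pa.marker.chrom, pa.marker.start, pb.marker.chrom, pb.marker.start,
             pa.element)
        )
    return pd.DataFrame(
        rows, columns=["marker_id", "chrom_a", "pos_a", "chrom_b", "pos_b", "element"]
    )
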