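"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected values by enumeration or exhaustive
search, not by calling the implementation under test.
"""

from __future__ import annotations

from itertools import permutations


def enumerate_mean_runs(n1: int, n2: int) -> float:
    """Mean run count over all distinct orderings of n1+n2 two-class labels."""
    labels = "a" * n1 + "b" * n2
    orderings = set(permutations(labels))
    total = 0
    for seq in orderings:
        total += 1 + sum(x != y for x, y in zip(seq, seq[1:]))
    return total / len(orderings)


def brute_force_shared_regions(
    classes: list[str],
    bin_size: int,
    merge_gap: int,
    min_region_length: int,
) -> list[tuple[int, int]]:
    """All maximal intervals satisfying the shared-region predicates.

    Bins are uniform ``bin_size``; classes are 'Q' (qualifying) or any
    non-Q gap class. An interval [i, j] over bins satisfies the
    predicates when bins i and j are qualifying, every internal maximal
    run of non-qualifying bins spans at most ``merge_gap`` bp, and the
    interval spans at least ``min_region_length`` bp. Maximal satisfying
    intervals are provably disjoint, so the result is the region list.
    """
    n = len(classes)

    def satisfies(i: int, j: int) -> bool:
        if classes[i] != "Q" or classes[j] != "Q":
            return False
        run = 0
        for k in range(i, j + 1):
            if classes[k] != "Q":
                run += bin_size
                if run > merge_gap:
                    return False
            else:
                run = 0
        return (j + 1 - i) * bin_size >= min_region_length

    sat = [(i, j) for i in range(n) for j in range(i, n) if satisfies(i, j)]
    maximal = [
        (i, j)
        for (i, j) in sat
        if not any(a <= i and j <= b and (a, b) != (i, j) for (a, b) in sat)
    ]
    return sorted((i * bin_size, (j + 1) * bin_size) for i, j in maximal)


def brute_force_n50(lengths: list[int]) -> int:
    """N50 by direct definition: shortest length in the smallest
    descending prefix whose cumulative sum reaches half the total."""
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for l in ordered:
        acc += l
        if acc >= half:
            return l
    raise AssertionError("unreachable for non-empty input")
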