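from __future__ import annotations

import numpy as np
import pytest

from karyoscope.genome_io import make_windows
from karyoscope.sexlink import NormalizedCoverageTrack
from karyoscope.synthetic_data import ElementSpec, FusionEvent, SimulationConfig

# N values realizing each bin class under the default caller parameters
CLASS_N = {
    "Q": (1.0, 1.0),   # male-diploid: ratio 1.0
    "F": (0.5, 1.0),   # female-dominated: ratio 0.5
    "M": (0.1, 0.1),   # low coverage in both sexes
}


def tracks_from_classes(classes, bin_size=100_000, chrom="cX"):
    """Build male/female normalized tracks whose X bins classify as given."""
    grid = make_windows({chrom: len(classes) * bin_size}, bin_size)
    n_m = np.array([CLASS_N[c][0] for c in classes])
    n_f = np.array([CLASS_N[c][1] for c in classes])

    def mk(sex, n):
        return NormalizedCoverageTrack(
            sample_id=f"sim_{sex}", sex=sex, windows=grid, depth=n * 30.0,
            N=n, autosomal_median_depth=30.0,
        )

    return mk("male", n_m), mk("female", n_f), chrom


@pytest.fixture
def tiny_config():
    """A small two-chromosome system (one X+D fusion) for fast fixture tests."""
    return SimulationConfig(
        elements={
            "A": ElementSpec(400_000, 20),
            "X": ElementSpec(250_000, 20),
            "D": ElementSpec(150_000, 20),
        },
        fusion_history=[FusionEvent("X", "D", inversions=0)],
        depth_mean=30.0,
        bin_size=10_000,
        telomere_repeats_per_end=50,
        seed=7,
    )
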