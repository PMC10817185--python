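import json
from dataclasses import replace

import numpy as np
import pytest

from karyoscope.genome_io import read_busco_markers, read_coverage_bed, read_het_snps
from karyoscope.nigon_paint import assign_nigon, intermixing_runs, ordered_element_labels
from karyoscope.seqfeatures import ends_capped, telomere_counts
from karyoscope.synthetic_data import (
    ElementSpec,
    FusionEvent,
    SimulationConfig,
    TruthSet,
    build_karyotype,
    preset,
    simulate_coverage,
    simulate_markers,
    simulate_sequences,
    simulate_snps,
    write_fixture_set,
)


class TestBuildKaryotype:
    def test_single_fusion_reduces_chromosome_count(self):
        cfg = preset("litomosoides")
        truth = build_karyotype(cfg)
        assert len(truth.karyotype) == 6  # 7 elements - 1 fusion
        assert truth.x_chrom == "chrX"
        assert truth.fused_components()["chrX"] == {"X", "D"}

    def test_chained_fusions(self):
        truth = build_karyotype(preset("onchocerca"))
        assert len(truth.karyotype) == 4  # 3 autosomes + X after 3 fusions
        assert truth.fused_components()["chrX"] == {"X", "D", "E"}
        assert any(
            comp == {"A", "N"} for comp in truth.fused_components().values()
        )

    def test_zero_inversions_keep_blocks_contiguous(self):
        cfg = replace(
            preset("litomosoides"),
            fusion_history=[FusionEvent("X", "D", inversions=0)],
        )
        truth = build_karyotype(cfg)
        assert [el for el, _ in truth.karyotype["chrX"]] == ["X", "D"]

    def test_refusing_joined_elements_is_an_error(self):
        cfg = replace(
            preset("litomosoides"),
            fusion_history=[
                FusionEvent("X", "D"),
                FusionEvent("D", "X"),
            ],
        )
        with pytest.raises(ValueError, match="already"):
            build_karyotype(cfg)

    def test_shared_region_must_be_ancestrally_autosomal(self):
        cfg = replace(preset("brugia"), shared_region=(0, 2_000_000))
        with pytest.raises(ValueError, match="autosomal"):
            build_karyotype(cfg)  # (0, 2 Mb) falls in X-derived sequence

    def test_inversions_conserve_element_content(self):
        cfg = preset("brugia", seed=3)
        truth = build_karyotype(cfg)
        got = {}
        for blocks in truth.karyotype.values():
            for el, length in blocks:
                got[el] = got.get(el, 0) + length
        want = {el: spec.bp for el, spec in cfg.elements.items()}
        assert got == want


class TestMarkers:
    def test_single_element_chromosomes_paint_pure(self, tiny_config):
        truth = build_karyotype(tiny_config)
        markers, nmap = simulate_markers(truth, tiny_config)
        painted = assign_nigon(markers, nmap)
        on_a = {p.element for p in painted if p.marker.chrom != "chrX"}
        assert on_a == {"A"}

    def test_marker_positions_lie_in_their_element_territory(self):
        cfg = preset("brugia", seed=5)
        truth = build_karyotype(cfg)
        markers, nmap = simulate_markers(truth, cfg)
        for m in markers:
            el = nmap[m.marker_id]
            territory = truth.element_territory(m.chrom, el)
            assert any(s <= m.start < e for s, e in territory)

    def test_marker_capacity_enforced(self):
        cfg = SimulationConfig(
            elements={"A": ElementSpec(1_000, 50), "X": ElementSpec(1_000, 1)},
        )
        with pytest.raises(ValueError, match="capacity"):
            simulate_markers(build_karyotype(cfg), cfg)


class TestIntermixing:
    def test_zero_inversion_fusion_is_partitioned(self):
        cfg = replace(
            preset("litomosoides", seed=1),
            fusion_history=[FusionEvent("X", "D", inversions=0)],
        )
        truth = build_karyotype(cfg)
        markers, nmap = simulate_markers(truth, cfg)
        labels = ordered_element_labels(assign_nigon(markers, nmap), "chrX")
        res = intermixing_runs(labels)
        assert res.runs == 2
        assert res.z_score <= -1.96
        assert res.verdict == "partitioned"

    def test_many_inversions_intermix(self):
        hits = 0
        for seed in range(20):
            cfg = preset("litomosoides", seed=seed)  # 200 inversions on X+D
            truth = build_karyotype(cfg)
            markers, nmap = simulate_markers(truth, cfg)
            labels = ordered_element_labels(assign_nigon(markers, nmap), "chrX")
            if abs(intermixing_runs(labels).z_score) < 1.96:
                hits += 1
        assert hits >= 18  # >= 90% of seeds


class TestCoverage:
    def test_expected_sexed_coverage_levels(self):
        cfg = preset("brugia", seed=2)
        truth = build_karyotype(cfg)
        male = simulate_coverage(truth, "male", cfg)
        female = simulate_coverage(truth, "female", cfg)
        auto = ~male.windows.chrom_mask(["chrX"])
        m_auto = np.median(male.depth[auto])
        off = male.windows.offset("chrX")
        s, e = truth.shared_region
        shared = [off + i for i, (st, en) in
                  enumerate(zip(*male.windows.bounds("chrX"))) if st >= s and en <= e]
        outside = [off + i for i in range(male.windows.n_windows("chrX"))
                   if off + i not in set(shared)]
        # ~26 shared bins: use the mean and a tolerance matching its
        # sampling noise (CV ~ 10% per bin)
        assert np.mean(male.depth[shared]) / m_auto == pytest.approx(1.0, abs=0.08)
        assert np.median(male.depth[outside]) / m_auto == pytest.approx(0.5, abs=0.05)
        # e = 0 for this preset: female X is fully diploid
        f_auto = np.median(female.depth[auto])
        f_x = np.median(female.depth[off : off + female.windows.n_windows("chrX")])
        assert f_x / f_auto == pytest.approx(1.0, abs=0.05)

    def test_embryo_dilution_scales_female_x(self):
        cfg = preset("litomosoides", seed=4)  # e = 0.8
        truth = build_karyotype(cfg)
        female = simulate_coverage(truth, "female", cfg)
        auto = ~female.windows.chrom_mask(["chrX"])
        off = female.windows.offset("chrX")
        nx = female.windows.n_windows("chrX")
        ratio = np.median(female.depth[off : off + nx]) / np.median(female.depth[auto])
        assert ratio == pytest.approx(1 - 0.8 / 4, abs=0.05)  # = 0.8

    def test_invalid_sex_rejected(self, tiny_config):
        truth = build_karyotype(tiny_config)
        with pytest.raises(ValueError, match="sex"):
            simulate_coverage(truth, "other", tiny_config)


class TestSnps:
    def test_rate_zero_gives_empty_table(self):
        cfg = replace(preset("brugia"), snp_rate_shared=0.0)
        truth = build_karyotype(cfg)
        assert len(simulate_snps(truth, cfg)) == 0

    def test_expected_count_scales_with_rate_and_span(self):
        cfg = preset("dirofilaria", seed=6)
        truth = build_karyotype(cfg)
        snps = simulate_snps(truth, cfg)
        s, e = truth.shared_region
        inside = snps.table[(snps.table["pos"] >= s) & (snps.table["pos"] < e)]
        expected = (e - s) * cfg.snp_rate_shared
        assert len(inside) == pytest.approx(expected, rel=0.05)

    def test_boundary_bin_density_is_boosted(self):
        cfg = preset("dirofilaria", seed=7)
        truth = build_karyotype(cfg)
        snps = simulate_snps(truth, cfg)
        s = truth.shared_region[0]
        boundary = snps.table[
            (snps.table["pos"] >= s - cfg.bin_size) & (snps.table["pos"] < s)
        ]
        rate = len(boundary) / cfg.bin_size
        want = cfg.snp_rate_shared * cfg.snp_rate_boundary_multiplier  # ~1/316 bp
        assert rate == pytest.approx(want, rel=0.35)  # Poisson noise at n ~ 316

    def test_degeneration_strata_carry_no_snps(self):
        cfg = replace(
            preset("dirofilaria"),
            degeneration_strata=[(14_000_000, 16_000_000)],
            seed=8,
        )
        truth = build_karyotype(cfg)
        snps = simulate_snps(truth, cfg)
        in_stratum = snps.table[
            (snps.table["pos"] >= 14_000_000) & (snps.table["pos"] < 16_000_000)
        ]
        assert len(in_stratum) == 0

    def test_strata_are_haploid_in_males(self):
        cfg = replace(
            preset("dirofilaria"),
            degeneration_strata=[(14_000_000, 16_000_000)],
            seed=8,
        )
        truth = build_karyotype(cfg)
        assert truth.male_x_ploidy(14_000_000, 16_000_000) == pytest.approx(1.0)
        assert truth.male_x_ploidy(17_000_000, 18_000_000) == pytest.approx(2.0)


class TestFixtureSet:
    def test_same_seed_reproduces_identical_manifest(self, tiny_config, tmp_path):
        m1 = write_fixture_set(tiny_config, tmp_path / "a")
        m2 = write_fixture_set(tiny_config, tmp_path / "b")
        assert m1 == m2
        m3 = write_fixture_set(replace(tiny_config, seed=8), tmp_path / "c")
        assert m3 != m1

    def test_emitted_files_round_trip_through_readers(self, tiny_config, tmp_path):
        cfg = replace(
            tiny_config,
            shared_region=(500_000, 700_000),
            snp_rate_shared=1e-3,
            fusion_history=[FusionEvent("X", "D", inversions=0)],
            elements={
                "A": ElementSpec(400_000, 20),
                "X": ElementSpec(250_000, 20),
                "D": ElementSpec(550_000, 20),
            },
        )
        out = tmp_path / "fx"
        write_fixture_set(cfg, out)
        truth = TruthSet.from_json((out / "truth.json").read_text())
        markers = read_busco_markers(out / "busco_full_table.tsv")
        assert len(markers) == 60
        cov = read_coverage_bed(out / "cov_male.bed", "m", "male")
        assert cov.windows.chrom_lengths == truth.chrom_lengths
        snps = read_het_snps(out / "snps_male.vcf", "sim_male")
        assert len(snps) > 0
        assert (snps.table["chrom"] == "chrX").all()

    def test_genome_ends_are_telomere_capped(self, tiny_config):
        truth = build_karyotype(tiny_config)
        seqs = simulate_sequences(truth, tiny_config)
        assert set(seqs) == set(truth.chrom_lengths)
        for chrom, seq in seqs.items():
            assert len(seq) == truth.chrom_lengths[chrom]
            assert ends_capped(telomere_counts(seq)) == (True, True)
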