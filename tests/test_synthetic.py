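import numpy as np
import pytest
from scipy import stats

from polpause.annotations import filter_isolated
from polpause.synthetic_data import (
    HISTONE_PARAMS,
    PA_PARAMS,
    OccupancyParams,
    apply_condition,
    genome_intensity,
    make_genome,
    occupancy_intensity,
    sample_reads,
    simulate_scenario,
)


class TestMakeGenome:
    def test_wide_spacing_all_isolated(self):
        sizes, gs, _ = make_genome(n_genes=10, spacing_range=(20_000, 30_000), seed=0)
        assert len(filter_isolated(gs, 4000)) == 10

    def test_histone_cluster_mode_none_isolated(self):
        sizes, gs, _ = make_genome(n_genes=10, spacing_range=(800, 1000), seed=0)
        assert len(filter_isolated(gs, 4000)) == 0

    def test_seed_determinism(self):
        _, a, _ = make_genome(n_genes=20, seed=5)
        _, b, _ = make_genome(n_genes=20, seed=5)
        assert a.genes == b.genes

    def test_class_mix_counts(self):
        _, gs, truth = make_genome(n_genes=100, class_mix={"core_histone": 0.3, "other": 0.7}, seed=1)
        counts = {c: sum(1 for v in truth.classes.values() if v == c) for c in ("core_histone", "other")}
        assert counts == {"core_histone": 30, "other": 70}

    def test_genes_within_chromosome_and_nonoverlapping(self):
        sizes, gs, _ = make_genome(n_genes=50, seed=2)
        ordered = sorted(gs.genes, key=lambda g: g.start)
        assert all(a.end < b.start for a, b in zip(ordered, ordered[1:]))
        assert ordered[-1].end <= sizes["chrS"]

    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError):
            make_genome(10, class_mix={"core_histone": 0.5, "other": 0.4})


class TestOccupancyIntensity:
    def test_pause_at_one_lambda(self):
        _, gs, _ = make_genome(n_genes=1, seed=0)
        g = gs.genes[0]
        p = OccupancyParams(tss_amplitude=0, body_level=0, background_rate=0, pause_amplitude=5, pause_decay_bp=300)
        v = occupancy_intensity(g, p, flank=8000)
        # value at distance lambda downstream is amplitude/e
        d = 300
        idx = (g.end - (g.start - 8000) - 1 + d) if g.strand == "+" else (g.start - (g.start - 8000) - d)
        assert v[idx] == pytest.approx(5 / np.e, rel=0.01)

    def test_mock_params_constant_background(self):
        _, gs, _ = make_genome(n_genes=1, seed=0)
        p = OccupancyParams(tss_amplitude=0, body_level=0, pause_amplitude=0, background_rate=0.07)
        v = occupancy_intensity(gs.genes[0], p, flank=8000)
        assert np.allclose(v, 0.07)

    def test_mass_matches_closed_form(self):
        """Numeric integral of the intensity equals the sum of the component
        closed forms (Gaussian mass + body + truncated-exponential pause +
        background)."""
        _, gs, _ = make_genome(n_genes=1, gene_length_range=(4000, 4000), seed=3)
        g = gs.genes[0]
        p = OccupancyParams()
        flank = 8000
        v = occupancy_intensity(g, p, flank=flank)
        total = v.sum()
        window = g.length + 2 * flank
        expected = (
            p.background_rate * window
            + p.tss_amplitude * p.tss_sd_bp * np.sqrt(2 * np.pi)
            + p.body_level * g.length
            + p.pause_amplitude * p.pause_decay_bp * (1 - np.exp(-p.pause_cap_bp / p.pause_decay_bp))
        )
        assert total == pytest.approx(expected, rel=0.01)

    def test_class_defaults(self):
        assert HISTONE_PARAMS.pause_decay_bp == 250 and HISTONE_PARAMS.pause_cap_bp == 1000
        assert PA_PARAMS.pause_decay_bp == 1500 and PA_PARAMS.pause_cap_bp == 8000

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            OccupancyParams(pause_decay_bp=0)
        with pytest.raises(ValueError):
            OccupancyParams(body_level=-1)


class TestSampleReads:
    def _intensity(self, seed=0):
        sizes, gs, truth = make_genome(n_genes=5, seed=seed)
        return sizes, gs, truth, *genome_intensity(sizes, gs, truth.params)

    def test_seed_determinism(self):
        _, _, _, intensity, _ = self._intensity()
        a = sample_reads(intensity, 1000, seed=9)
        b = sample_reads(intensity, 1000, seed=9)
        assert a == b

    def test_total_count_poisson(self):
        _, _, _, intensity, _ = self._intensity()
        n = len(sample_reads(intensity, 10_000, seed=1))
        lo, hi = stats.poisson.ppf([0.0005, 0.9995], 10_000)
        assert lo <= n <= hi

    def test_read_length_32(self):
        _, _, _, intensity, _ = self._intensity()
        reads = sample_reads(intensity, 500, seed=2)
        interior = [r for r in reads if r.start > 40]
        assert all(r.length == 32 for r in interior)

    def test_nascent_zero_background_sense_only(self):
        sizes, gs, truth, _, _ = self._intensity()
        intensity, owner = genome_intensity(sizes, gs, truth.params, background_rate=0.0)
        reads = sample_reads(intensity, 2000, mode="nascent", seed=3, owner=owner)
        strand_of = {g.name: g.strand for g in gs}
        for r in reads:
            covering = [g for g in gs if g.start - 9000 < r.start < g.end + 9000]
            assert covering and r.strand == strand_of[covering[0].name]

    def test_zero_mass_errors(self):
        with pytest.raises(ValueError, match="zero-mass"):
            sample_reads({"c": np.zeros(100)}, 100)


class TestApplyCondition:
    def test_pa_scaled_histone_untouched(self):
        _, _, truth = make_genome(n_genes=20, seed=4)
        new = apply_condition(truth, gamma_downstream=2.0, delta_tss=0.5)
        for g, cls in truth.classes.items():
            old_p, new_p = truth.params[g], new.params[g]
            if cls == "core_histone":
                assert new_p == old_p
            else:
                assert new_p.pause_amplitude == pytest.approx(2 * old_p.pause_amplitude)
                assert new_p.tss_amplitude == pytest.approx(0.5 * old_p.tss_amplitude)

    def test_identity_roundtrip(self):
        _, _, truth = make_genome(n_genes=10, seed=4)
        new = apply_condition(truth, 1.0, 1.0)
        assert new.params == truth.params

    def test_invalid_factors(self):
        _, _, truth = make_genome(n_genes=2, seed=0)
        with pytest.raises(ValueError):
            apply_condition(truth, 0.0, 1.0)


class TestScenario:
    def test_full_path_determinism(self):
        a = simulate_scenario(n_genes=20, seed=11)
        b = simulate_scenario(n_genes=20, seed=11)
        assert a.reads == b.reads and a.genes.genes == b.genes.genes

    def test_coverage_converges_to_smoothed_intensity(self):
        """Binned sampled coverage converges to the extension-smoothed
        planted intensity (correlation rises above 0.95 at high depth)."""
        from polpause.coverage import build_coverage, extend_reads
        from polpause.synthetic_data import genome_intensity

        sc = simulate_scenario(n_genes=20, reads_per_gene=1000, seed=2)
        sizes = sc.chrom_sizes
        sig = build_coverage(extend_reads(sc.reads["polii"], 200, sizes), 50, sizes)
        intensity, _ = genome_intensity(sizes, sc.genes, sc.truth.params)
        I = intensity["chrS"]
        kernel = np.ones(400) / 400  # +/-200 bp both-strand extension box
        smooth = np.convolve(I, kernel, mode="same")
        n = len(sig.covered["chrS"]) * 50
        smooth = np.pad(smooth, (0, n - len(smooth)))[:n]
        binned = smooth.reshape(-1, 50).mean(axis=1)
        r = np.corrcoef(binned, sig.values("chrS"))[0, 1]
        assert r >= 0.95

    def test_truth_written_before_reads(self, scenario):
        assert set(scenario.truth.params) == set(scenario.genes.names())
        assert scenario.truth.read_length == 32

    def test_scenario_files_roundtrip(self, tmp_path):
        from polpause.coverage import read_bed6, read_chrom_sizes
        from polpause.annotations import read_gene_models
        from polpause.synthetic_data import write_scenario

        sc = simulate_scenario(n_genes=10, seed=3)
        write_scenario(sc, str(tmp_path))
        sizes = read_chrom_sizes(str(tmp_path / "chrom.sizes"))
        assert sizes == sc.chrom_sizes
        gs = read_gene_models(str(tmp_path / "genes.bed12"), "bed12")
        assert [g.name for g in gs] == sc.genes.names()
        assert [(g.start, g.end, g.strand) for g in gs] == [
            (g.start, g.end, g.strand) for g in sc.genes
        ]
        reads = read_bed6(str(tmp_path / "polii.bed"))
        assert [(r.chrom, r.start, r.end, r.strand) for r in reads] == [
            (r.chrom, r.start, r.end, r.strand) for r in sc.reads["polii"]
        ]
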