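import numpy as np
import pytest

from polpause.annotations import GeneModel, GeneSet
from polpause.coverage import (
    Fragment,
    ReadAlignment,
    anchor_matrix,
    build_coverage,
    extend_reads,
    mean_profile,
    scaled_gene_matrix,
)

SIZES = {"chr1": 100_000}


class TestExtendReads:
    @pytest.mark.parametrize(
        "read,expected",
        [
            (ReadAlignment("chr1", 1000, 1032, "+"), (1000, 1200)),
            (ReadAlignment("chr1", 5000, 5032, "-"), (4832, 5032)),
            (ReadAlignment("chr1", 10, 42, "-"), (0, 42)),  # clipped at chromosome start
        ],
    )
    def test_extension_rule(self, read, expected):
        (f,) = extend_reads([read], 200, SIZES)
        assert (f.start, f.end) == expected

    def test_long_read_keeps_native_length(self):
        (f,) = extend_reads([ReadAlignment("chr1", 0, 300, "+")], 200, SIZES)
        assert f.length == 300

    def test_out_of_bounds_read_errors(self):
        with pytest.raises(ValueError, match="read 0"):
            extend_reads([ReadAlignment("chr1", 99_990, 100_022, "+")], 200, SIZES)


class TestBuildCoverage:
    def test_aligned_fragment_fills_bins(self):
        t = build_coverage([Fragment("chr1", 1000, 1200, "+")], 50, SIZES)
        v = t.values("chr1")
        assert np.array_equal(np.nonzero(v)[0], [20, 21, 22, 23])
        assert np.allclose(v[20:24], 1.0)

    def test_partial_bin_overlap(self):
        t = build_coverage([Fragment("chr1", 1025, 1225, "+")], 50, SIZES)
        v = t.values("chr1")
        assert np.allclose(v[20:25], [0.5, 1.0, 1.0, 1.0, 0.5])

    def test_matches_per_base_oracle(self, rng):
        """Binned values equal a brute-force per-base depth array aggregated
        to bins, over many random fragment sets."""
        for _ in range(20):
            n = int(rng.integers(1, 500))
            starts = rng.integers(0, 9_000, size=n)
            lens = rng.integers(1, 400, size=n)
            frags = [
                Fragment("c", int(s), int(min(s + l, 10_000)), "+" if rng.random() < 0.5 else "-")
                for s, l in zip(starts, lens)
            ]
            w = int(rng.choice([1, 7, 50]))
            t = build_coverage(frags, w, {"c": 10_000})
            depth = np.zeros(10_000)
            for f in frags:
                depth[f.start : f.end] += 1
            n_bins = -(-10_000 // w)
            padded = np.zeros(n_bins * w)
            padded[:10_000] = depth
            oracle = padded.reshape(n_bins, w).sum(axis=1) / w
            assert np.array_equal(t.values("c"), oracle)

    def test_base_pair_conservation_exact(self, rng):
        frags = [
            Fragment("chr1", int(s), int(s) + 200, "+")
            for s in rng.integers(0, 99_800, size=1000)
        ]
        t = build_coverage(frags, 50, SIZES)
        assert t.total_covered_bp() == sum(f.length for f in frags)

    def test_strand_mode_filters(self):
        frags = [Fragment("chr1", 0, 100, "+"), Fragment("chr1", 0, 100, "-")]
        assert build_coverage(frags, 50, SIZES, strand_mode="plus").total_fragments == 1
        assert build_coverage(frags, 50, SIZES, strand_mode="both").total_fragments == 2

    def test_rpm_requires_fragments(self):
        with pytest.raises(ValueError, match="rpm"):
            build_coverage([], 50, SIZES, normalization="rpm")

    def test_rpm_scaling(self):
        frags = [Fragment("chr1", 0, 200, "+")] * 4
        raw = build_coverage(frags, 50, SIZES, normalization="raw")
        rpm = build_coverage(frags, 50, SIZES, normalization="rpm")
        assert np.allclose(rpm.values("chr1"), raw.values("chr1") * 1e6 / 4)


def _uniform_track(value=2.0, w=50, size=100_000):
    # value fragments of depth `value` everywhere: fabricate covered array
    from polpause.coverage import CoverageTrack

    n_bins = size // w
    covered = {"chr1": np.full(n_bins, int(value * w), dtype=np.int64)}
    return CoverageTrack(w, {"chr1": size}, covered, total_fragments=1000)


class TestAnchorMatrix:
    def _gs(self, *genes):
        return GeneSet(list(genes))

    def test_plus_strand_column_mapping(self):
        # single fragment exactly in [10000, 10050): shows up in column 80
        t = build_coverage([Fragment("chr1", 10_000, 10_050, "+")], 50, SIZES)
        g = GeneModel("chr1", 4000, 10_000, "+", "gp", "gp")
        m = anchor_matrix(t, self._gs(g), "EAG", 4000)
        assert m.n_bins == 160
        assert m.values[0, 80] == 1.0 and m.values[0].sum() == 1.0

    def test_minus_strand_orientation(self):
        # minus gene starting at 10000: first downstream bin is genomic [9950, 10000)
        t = build_coverage([Fragment("chr1", 9_950, 10_000, "+")], 50, SIZES)
        g = GeneModel("chr1", 10_000, 16_000, "-", "gm", "gm")
        m = anchor_matrix(t, self._gs(g), "EAG", 4000)
        assert m.values[0, 80] == 1.0 and m.values[0].sum() == 1.0

    def test_uniform_track_constant_matrix(self):
        t = _uniform_track(2.0)
        g1 = GeneModel("chr1", 20_000, 24_000, "+", "a", "a")
        g2 = GeneModel("chr1", 50_000, 52_345, "-", "b", "b")
        m = anchor_matrix(t, self._gs(g1, g2), "EAG", 4000)
        assert np.allclose(m.values, 2.0)

    def test_gene_off_track_dropped(self):
        t = _uniform_track()
        g = GeneModel("chrX", 0, 100, "+", "x", "x")
        m = anchor_matrix(t, self._gs(g), "EAG", 4000)
        assert m.n_genes == 0 and m.dropped == ["x"]

    def test_out_of_chromosome_zero_filled_and_flagged(self):
        t = _uniform_track(1.0)
        g = GeneModel("chr1", 500, 1500, "-", "edge", "edge")  # window reaches below 0
        m = anchor_matrix(t, self._gs(g), "EAG", 4000)
        assert m.clipped[0]
        assert np.all(m.values[0][m.values[0] == 0] == 0)

    def test_strand_flip_mirror_bitwise(self, rng):
        """Mirroring the genome and flipping strands leaves the matrix bitwise
        identical (rows map to the same genes)."""
        L = 100_000
        frags = [
            Fragment("chr1", int(s), int(s + l), "+" if rng.random() < 0.5 else "-")
            for s, l in zip(rng.integers(0, L - 400, 2000), rng.integers(30, 400, 2000))
        ]
        genes = []
        for i in range(12):
            s = 4000 + i * 7000 + int(rng.integers(0, 500))
            genes.append(
                GeneModel("chr1", s, s + int(rng.integers(800, 3000)), "+" if i % 2 else "-", f"g{i}", f"g{i}")
            )
        t = build_coverage(frags, 50, {"chr1": L})
        m = anchor_matrix(t, GeneSet(genes), "EAG", 4000)

        m_frags = [Fragment("chr1", L - f.end, L - f.start, "-" if f.strand == "+" else "+") for f in frags]
        m_genes = [
            GeneModel("chr1", L - g.end, L - g.start, "-" if g.strand == "+" else "+", g.name, g.name)
            for g in genes
        ]
        mt = build_coverage(m_frags, 50, {"chr1": L})
        mm = anchor_matrix(mt, GeneSet(m_genes), "EAG", 4000)
        assert m.genes == mm.genes
        assert np.array_equal(m.values, mm.values)
        # TSS anchor obeys the same symmetry
        a = anchor_matrix(t, GeneSet(genes), "TSS", 4000)
        b = anchor_matrix(mt, GeneSet(m_genes), "TSS", 4000)
        assert np.array_equal(a.values, b.values)


class TestScaledGeneMatrix:
    def test_uniform_track_flat_profile(self):
        t = _uniform_track(3.0)
        g = GeneModel("chr1", 20_000, 26_000, "+", "a", "a")
        m = scaled_gene_matrix(t, GeneSet([g]), n_body_bins=100, flank_bp=4000)
        assert np.allclose(m.values, 3.0)

    def test_exact_length_matches_fixed_width(self, rng):
        frags = [Fragment("chr1", int(s), int(s) + 200, "+") for s in rng.integers(15_000, 30_000, 500)]
        t = build_coverage(frags, 50, SIZES)
        g = GeneModel("chr1", 20_000, 25_000, "+", "a", "a")  # 100 bins x 50 bp
        m = scaled_gene_matrix(t, GeneSet([g]), n_body_bins=100, flank_bp=1000)
        # body bins must equal direct 50-bp window means
        direct = [t.covered["chr1"][(20_000 + i * 50) // 50] * t.scale for i in range(100)]
        assert np.allclose(m.values[0, 20:120], direct)

    def test_body_bins_match_bruteforce_means(self, rng):
        frags = [
            Fragment("chr1", int(s), int(s + l), "+")
            for s, l in zip(rng.integers(15_000, 30_000, 800), rng.integers(50, 300, 800))
        ]
        t = build_coverage(frags, 50, SIZES)
        g = GeneModel("chr1", 20_000, 23_731, "-", "a", "a")
        n_body = 37
        m = scaled_gene_matrix(t, GeneSet([g]), n_body_bins=n_body, flank_bp=1000)
        per_base = np.repeat(t.values("chr1"), 50)
        L = g.length
        cuts = [g.end - (i * L) // n_body for i in range(n_body + 1)]
        oracle = [per_base[cuts[i + 1] : cuts[i]].mean() for i in range(n_body)]
        assert np.allclose(m.values[0, 20 : 20 + n_body], oracle)

    def test_short_gene_dropped(self):
        t = _uniform_track()
        g = GeneModel("chr1", 20_000, 20_050, "+", "tiny", "tiny")
        m = scaled_gene_matrix(t, GeneSet([g]), n_body_bins=100, flank_bp=1000)
        assert m.n_genes == 0 and m.dropped == ["tiny"]


class TestMeanProfile:
    def test_examples_and_linearity(self):
        from polpause.coverage import AnchorMatrix

        m = AnchorMatrix(["a", "b"], "EAG", 50, 50, np.array([[0.0, 2.0], [4.0, 0.0]]))
        assert np.allclose(mean_profile(m), [2.0, 1.0])
        assert np.allclose(mean_profile(m, ["a"]), [0.0, 2.0])
        # weighted mean of a partition's means equals the global mean
        part = 0.5 * mean_profile(m, ["a"]) + 0.5 * mean_profile(m, ["b"])
        assert np.allclose(part, mean_profile(m))

    def test_empty_subset_errors(self):
        from polpause.coverage import AnchorMatrix

        m = AnchorMatrix(["a"], "EAG", 50, 50, np.ones((1, 2)))
        with pytest.raises(ValueError):
            mean_profile(m, [])
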