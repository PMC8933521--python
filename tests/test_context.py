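"""Genomic-distribution analyses: region breakdown, uniformity, overlap and
the Smith-Waterman similarity screen (with a brute-force affine-gap DP
oracle)."""

import numpy as np
import pytest

import gotipipe as gp


def uniform_snv_set(genome, n, rng, sample_id="s"):
    """n distinct SNVs placed uniformly over the nuclear contigs."""
    names = genome.nuclear_names
    weights = np.array([len(genome.contigs[c]) for c in names], dtype=float)
    weights /= weights.sum()
    calls = {}
    while len(calls) < n:
        contig = names[int(rng.choice(len(names), p=weights))]
        pos = int(rng.integers(1, len(genome.contigs[contig]) + 1))
        ref = genome.contigs[contig][pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        calls[(contig, pos, ref, alt)] = gp.VariantCall(contig, pos, ref, alt, 10, 20)
    return gp.DeNovoSet(sample_id, calls)


class TestRegionBreakdown:
    def test_whole_genome_transcribed(self, small_genome):
        rng = np.random.default_rng(1)
        snvs = uniform_snv_set(small_genome, 50, rng)
        full = [
            gp.Annotation(c, 0, len(small_genome.contigs[c]), "+", "transcribed", "g")
            for c in small_genome.nuclear_names
        ]
        res = gp.region_breakdown(snvs, full, small_genome)
        assert res.per_sample["in_fraction"].iloc[0] == 1.0
        assert res.transcribed_fraction == 1.0

    def test_no_intervals(self, small_genome):
        rng = np.random.default_rng(2)
        snvs = uniform_snv_set(small_genome, 50, rng)
        res = gp.region_breakdown(snvs, [], small_genome)
        assert res.per_sample["in_fraction"].iloc[0] == 0.0

    def test_in_out_conservation(self, small_genome):
        rng = np.random.default_rng(3)
        sets = [uniform_snv_set(small_genome, 80, rng, f"s{i}") for i in range(3)]
        res = gp.region_breakdown(
            sets, small_genome.annotations_of("transcribed"), small_genome
        )
        for _, row in res.per_sample.iterrows():
            assert row["n_in"] + row["n_out"] == row["n"]

    def test_binomial_mean_recovery(self, small_genome):
        """Uniform SNVs land in transcribed territory at the genomic fraction."""
        frac = 0.4
        intervals = [
            gp.Annotation(c, 0, int(len(small_genome.contigs[c]) * frac), "+",
                          "transcribed", "g")
            for c in small_genome.nuclear_names
        ]
        rng = np.random.default_rng(4)
        fracs = []
        for _ in range(100):
            snvs = uniform_snv_set(small_genome, 500, rng)
            res = gp.region_breakdown(snvs, intervals, small_genome)
            fracs.append(res.per_sample["in_fraction"].iloc[0])
        assert abs(np.mean(fracs) - frac) < 0.02

    def test_group_comparison_runs(self, small_genome):
        rng = np.random.default_rng(5)
        sets = [uniform_snv_set(small_genome, 60, rng, f"s{i}") for i in range(4)]
        res = gp.region_breakdown(
            sets, small_genome.annotations_of("transcribed"), small_genome,
            groups=["a", "a", "b", "b"],
        )
        assert res.group_test is not None
        assert 0 < res.group_test.p <= 1

    def test_unknown_contig_rejected(self, small_genome):
        rng = np.random.default_rng(6)
        snvs = uniform_snv_set(small_genome, 10, rng)
        bad = [gp.Annotation("chr99", 0, 100, "+", "transcribed", "g")]
        with pytest.raises(ValueError, match="unknown contig"):
            gp.region_breakdown(snvs, bad, small_genome)


class TestUniformity:
    def test_clustered_snvs_rejected(self, small_genome):
        """Everything piled into one bin gives an extreme chi-square."""
        calls = {}
        seq = small_genome.contigs["chr1"]
        for i in range(200):
            pos = 1000 + i
            ref = seq[pos - 1]
            alt = "A" if ref != "A" else "C"
            calls[("chr1", pos, ref, alt)] = gp.VariantCall("chr1", pos, ref, alt, 10, 20)
        res = gp.uniformity_test(gp.DeNovoSet("s", calls), small_genome, bin_size=10_000)
        assert res.p_value < 1e-6

    def test_single_bin_non_rejecting(self, small_genome):
        rng = np.random.default_rng(7)
        snvs = uniform_snv_set(small_genome, 20, rng)
        res = gp.uniformity_test(snvs, small_genome, bin_size=10**9)
        assert res.p_value == 1.0 and res.df <= 1

    def test_type_i_error_calibrated(self, small_genome):
        """Uniform placement is rejected at ~the nominal 5% rate."""
        rng = np.random.default_rng(8)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            snvs = uniform_snv_set(small_genome, 300, rng)
            if gp.uniformity_test(snvs, small_genome, bin_size=10_000).p_value < 0.05:
                rejections += 1
        assert rejections / n_rep <= 0.10 + 0.04

    def test_empty_set_rejected(self, small_genome):
        with pytest.raises(ValueError):
            gp.uniformity_test(gp.DeNovoSet("empty"), small_genome)


class TestOverlap:
    def test_identical_sets(self, small_genome):
        rng = np.random.default_rng(9)
        s = uniform_snv_set(small_genome, 40, rng)
        t = gp.DeNovoSet("t", dict(s.calls))
        rep = gp.cross_sample_overlap([s, t], small_genome)
        assert rep.pairwise[(0, 1)] == 40
        assert rep.k_way == 40

    def test_disjoint_sets(self, small_genome):
        rng = np.random.default_rng(10)
        a = uniform_snv_set(small_genome, 30, rng, "a")
        b = gp.DeNovoSet(
            "b",
            {k: c for k, c in uniform_snv_set(small_genome, 60, rng, "b").calls.items()
             if k not in a.calls},
        )
        rep = gp.cross_sample_overlap([a, b], small_genome)
        assert rep.pairwise[(0, 1)] == 0

    def test_expectation_formula_against_monte_carlo(self, small_genome):
        """n_i n_j / G matches the empirical mean overlap of uniform sets."""
        rng = np.random.default_rng(11)
        n = 2_000  # large n so the expectation is >> 0 on 200 kb
        expected = None
        overlaps = []
        for _ in range(40):
            a = uniform_snv_set(small_genome, n, rng, "a")
            b = uniform_snv_set(small_genome, n, rng, "b")
            rep = gp.cross_sample_overlap([a, b], small_genome, key_mode="position")
            overlaps.append(rep.pairwise[(0, 1)])
            expected = rep.expected_pairwise[(0, 1)]
        ratio = np.mean(overlaps) / expected
        assert 0.5 < ratio < 2.0

    def test_position_mode_coarser_than_full(self, small_genome):
        rng = np.random.default_rng(12)
        a = uniform_snv_set(small_genome, 500, rng, "a")
        b = uniform_snv_set(small_genome, 500, rng, "b")
        full = gp.cross_sample_overlap([a, b], small_genome).pairwise[(0, 1)]
        loose = gp.cross_sample_overlap([a, b], small_genome,
                                        key_mode="position").pairwise[(0, 1)]
        assert full <= loose

    def test_fewer_than_two_sets_rejected(self, small_genome):
        with pytest.raises(ValueError):
            gp.cross_sample_overlap([gp.DeNovoSet("a")], small_genome)


# ---------------------------------------------------------------------------
# Smith-Waterman oracle: affine-gap local alignment DP (Gotoh), first gap
# base costs 2, each extension 1 — matching the package's scoring scheme.


def sw_oracle(a: str, b: str) -> float:
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (horizontal)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - 2, E[i, j - 1] - 1)
            F[i, j] = max(H[i - 1, j] - 2, F[i - 1, j] - 1)
            s = 1 if a[i - 1] == b[j - 1] else -1
            H[i, j] = max(0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


class TestSmithWaterman:
    def test_perfect_match_scores_length(self):
        s = "ACGTACGTAC"
        assert gp.smith_waterman_score(s, s) == len(s)

    def test_no_common_substring(self):
        assert gp.smith_waterman_score("ACGTACGT", "TTTTTTTT") <= 1

    def test_matches_dp_oracle_on_random_pairs(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 13))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 13))))
            assert gp.smith_waterman_score(a, b) == sw_oracle(a, b)

    def test_score_bounded_by_query_length(self):
        rng = np.random.default_rng(14)
        for _ in range(50):
            a = "".join(rng.choice(list("ACGT"), size=20))
            b = "".join(rng.choice(list("ACGT"), size=30))
            assert 0 <= gp.smith_waterman_score(a, b) <= min(len(a), len(b))


class TestSimilarityScreen:
    def test_verbatim_target_flank_scores_full_length(self, small_genome, target):
        """An off-target flank identical to the target region scores its length."""
        mito = small_genome.mito_name
        region = small_genome.window(mito, target.position, 20)
        # plant the target region inside chr1 (fresh copy of the assembly)
        seq = small_genome.contigs["chr1"]
        planted = seq[:5000] + region + seq[5000 + len(region):]
        genome = gp.GenomeAssembly(
            contigs={"chr1": planted, "chrM": small_genome.contigs[mito]},
            mito_name="chrM",
        )
        pos = 5000 + 21  # center of the planted region, 1-based
        ref = planted[pos - 1]
        alt = "T" if ref != "T" else "A"
        snvs = gp.DeNovoSet.from_calls(
            "s", [gp.VariantCall("chr1", pos, ref, alt, 10, 20)]
        )
        rep = gp.similarity_screen(snvs, genome, [region], flank=20, seed=1)
        assert rep.per_snv["score"].iloc[0] == len(region)

    def test_snv_inside_numt_flagged(self, small_genome):
        numt = small_genome.annotations_of("NUMT")[0]
        pos = numt.start + numt.length // 2 + 1
        ref = small_genome.contigs[numt.contig][pos - 1]
        alt = "T" if ref != "T" else "A"
        snvs = gp.DeNovoSet.from_calls(
            "s", [gp.VariantCall(numt.contig, pos, ref, alt, 10, 20)]
        )
        rep = gp.similarity_screen(snvs, small_genome, ["ACGTACGTACGTACGT"],
                                   flank=15, seed=2)
        assert bool(rep.per_snv["in_numt"].iloc[0])
        assert rep.n_numt_hits == 1

    def test_clipped_flank_flagged(self, small_genome):
        ref = small_genome.contigs["chr1"][2]
        alt = "T" if ref != "T" else "A"
        snvs = gp.DeNovoSet.from_calls(
            "s", [gp.VariantCall("chr1", 3, ref, alt, 10, 20)]
        )
        rep = gp.similarity_screen(snvs, small_genome, ["ACGTACGTACGTACGT"],
                                   flank=15, seed=3)
        assert bool(rep.per_snv["clipped"].iloc[0])

    def test_null_scores_seeded_and_sized(self, small_genome):
        rng = np.random.default_rng(15)
        snvs = uniform_snv_set(small_genome, 20, rng)
        rep1 = gp.similarity_screen(snvs, small_genome, ["ACGTACGTACGTACGTACGT"],
                                    flank=15, seed=7, null_multiplier=5)
        rep2 = gp.similarity_screen(snvs, small_genome, ["ACGTACGTACGTACGTACGT"],
                                    flank=15, seed=7, null_multiplier=5)
        assert len(rep1.null_scores) == 5 * 20
        assert (rep1.null_scores == rep2.null_scores).all()

    def test_requires_targets_and_min_flank(self, small_genome):
        rng = np.random.default_rng(16)
        snvs = uniform_snv_set(small_genome, 5, rng)
        with pytest.raises(ValueError):
            gp.similarity_screen(snvs, small_genome, [], flank=15, seed=0)
        with pytest.raises(ValueError):
            gp.similarity_screen(snvs, small_genome, ["ACGT"], flank=5, seed=0)
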