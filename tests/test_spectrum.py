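"""Spectrum, logo, motif-enrichment and t-test, with exact-enumeration
oracles for the Fisher test and an incomplete-beta-free t-test route."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import gotipipe as gp
from gotipipe.simulate import SUB_CLASSES


def call(contig, pos, ref, alt):
    return gp.VariantCall(contig, pos, ref, alt, 10, 20)


class TestClassifySubstitution:
    def test_pyrimidine_identity(self):
        assert gp.classify_substitution("C", "T") == "C>T"

    def test_purine_reverse_complemented(self):
        assert gp.classify_substitution("G", "A") == "C>T"
        assert gp.classify_substitution("A", "G") == "T>C"

    def test_exhaustive_two_to_one_map(self):
        """All 12 ordered substitutions map 2-to-1 onto the 6 classes."""
        hits = {c: 0 for c in SUB_CLASSES}
        for ref, alt in itertools.permutations("ACGT", 2):
            hits[gp.classify_substitution(ref, alt)] += 1
        assert all(n == 2 for n in hits.values())

    @pytest.mark.parametrize("ref,alt", [("C", "C"), ("N", "A"), ("C", "N")])
    def test_bad_inputs_rejected(self, ref, alt):
        with pytest.raises(ValueError):
            gp.classify_substitution(ref, alt)


class TestSpectrum:
    def test_proportions_from_counts(self):
        calls = [call("c", i + 1, "C", "T") for i in range(5)]
        calls += [call("c", i + 10, "G", "A") for i in range(4)]
        calls += [call("c", 100, "T", "C")]
        res = gp.spectrum(gp.DeNovoSet.from_calls("s", calls))
        assert res.n == 10
        assert res.proportions["C>T"] == pytest.approx(0.9)
        assert gp.ct_fraction(gp.DeNovoSet.from_calls("s", calls)) == pytest.approx(0.9)

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(3)
        calls = []
        for i in range(137):
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            calls.append(call("c", i + 1, str(ref), str(alt)))
        res = gp.spectrum(gp.DeNovoSet.from_calls("s", calls))
        assert sum(res.proportions.values()) == pytest.approx(1.0)

    def test_empty_set_flagged(self):
        res = gp.spectrum(gp.DeNovoSet("empty"))
        assert res.empty and res.n == 0
        with pytest.raises(ValueError):
            gp.ct_fraction(gp.DeNovoSet("empty"))

    def test_indels_ignored(self):
        calls = [call("c", 1, "C", "T"), gp.VariantCall("c", 2, "A", "DEL", 5, 10)]
        assert gp.spectrum(gp.DeNovoSet.from_calls("s", calls)).n == 1

    def test_simulation_recovery(self, small_genome, target):
        """Injected 0.90 C>T weight is recovered from the truth spectrum."""
        truth = gp.inject_edits(small_genome, target,
                                gp.EditingModel(lambda_nuclear=500), seed=31)
        offs = [call(e.contig, e.position, e.ref, e.alt)
                for e in truth.by_compartment("nuclear_offtarget")]
        frac = gp.ct_fraction(gp.DeNovoSet.from_calls("s", offs))
        assert abs(frac - 0.90) < 0.04


class TestExtractContexts:
    def test_window_matches_flank_verbatim(self, toy_genome):
        seq = toy_genome.contigs["chr1"]
        pos = next(i for i in range(20, 40) if seq[i - 1] == "C")
        ctx = gp.extract_contexts(
            toy_genome, [call("chr1", pos, "C", "T")], half_width=5
        )
        want = seq[pos - 6 : pos + 5]
        for k, b in enumerate(want):
            col = ctx.counts[k]
            assert col["ACGT".index(b)] == 1 and col.sum() == 1

    def test_g_record_reverse_complemented(self, toy_genome):
        """A site recorded as G>A yields the revcomp of the plus-strand window."""
        seq = toy_genome.contigs["chr1"]
        pos = next(i for i in range(20, 40) if seq[i - 1] == "G")
        ctx = gp.extract_contexts(
            toy_genome, [call("chr1", pos, "G", "A")], half_width=5
        )
        want = gp.revcomp(seq[pos - 6 : pos + 5])
        assert want[5] == "C"
        for k, b in enumerate(want):
            assert ctx.counts[k]["ACGT".index(b)] == 1

    def test_strand_invariance(self, small_genome):
        """The context matrix of C>T records equals that of their G>A mirror
        images on the reverse-complemented genome."""
        seq = small_genome.contigs["chr1"]
        L = len(seq)
        pos_c = [i + 1 for i in range(50, 5000) if seq[i] == "C"][:40]
        plus = [call("chr1", p, "C", "T") for p in pos_c]
        mirror_genome = gp.GenomeAssembly(
            contigs={"chr1": gp.revcomp(seq),
                     "chrM": small_genome.contigs[small_genome.mito_name]},
            mito_name="chrM",
        )
        mirror = [call("chr1", L - p + 1, "G", "A") for p in pos_c]
        a = gp.extract_contexts(small_genome, plus, 10)
        b = gp.extract_contexts(mirror_genome, mirror, 10)
        assert (a.counts == b.counts).all()

    def test_circular_mito_window_wraps(self, small_genome):
        mito = small_genome.mito_name
        seq = small_genome.contigs[mito]
        pos = next(i + 1 for i in range(0, 5) if seq[i] == "C")
        ctx = gp.extract_contexts(small_genome, [call(mito, pos, "C", "T")], 10)
        assert ctx.n_rows == 1 and ctx.n_dropped == 0

    def test_linear_edge_dropped_and_counted(self, small_genome):
        seq = small_genome.contigs["chr1"]
        pos = next(i + 1 for i in range(0, 5) if seq[i] in "CG")
        ref = seq[pos - 1]
        alt = "T" if ref == "C" else "A"
        ctx = gp.extract_contexts(small_genome, [call("chr1", pos, ref, alt)], 10)
        assert ctx.n_rows == 0 and ctx.n_dropped == 1

    def test_non_ct_records_ignored(self, small_genome):
        seq = small_genome.contigs["chr1"]
        pos = next(i + 1 for i in range(50, 100) if seq[i - 1] == "T")
        ctx = gp.extract_contexts(small_genome, [call("chr1", pos, "T", "A")], 10)
        assert ctx.n_rows == 0


class TestLogoBits:
    def _ctx(self, counts):
        arr = np.array(counts)
        return gp.ContextMatrix(half_width=(len(arr) - 1) // 2, counts=arr,
                                n_rows=int(arr[0].sum()))

    def test_uniform_column_zero_bits(self):
        res = gp.logo_bits(self._ctx([[25, 25, 25, 25]]))
        assert res.information[0] == pytest.approx(0.0)

    def test_single_base_column_two_bits(self):
        res = gp.logo_bits(self._ctx([[0, 100, 0, 0]]))
        assert res.information[0] == pytest.approx(2.0)

    def test_fifty_fifty_one_bit(self):
        res = gp.logo_bits(self._ctx([[50, 0, 0, 50]]))
        assert res.information[0] == pytest.approx(1.0)

    def test_bounds_and_letter_heights(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, size=(21, 4))
        counts[:, 0] += 1  # no empty columns
        ctx = gp.ContextMatrix(10, counts, n_rows=int(counts[0].sum()))
        res = gp.logo_bits(ctx)
        assert ((res.information >= 0) & (res.information <= 2)).all()
        assert np.allclose(res.letter_heights.sum(axis=1), res.information)

    def test_small_sample_correction_shrinks_ic(self):
        ctx = self._ctx([[0, 10, 0, 0]])
        raw = gp.logo_bits(ctx).information[0]
        corrected = gp.logo_bits(ctx, small_sample_correction=True).information[0]
        assert corrected < raw

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            gp.logo_bits(gp.ContextMatrix(1, np.zeros((3, 4), dtype=int), 0))


def fisher_two_sided_oracle(table) -> float:
    """Two-sided Fisher p by hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            math.comb(col1, x) * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    p_obs = prob(a)
    lo, hi = max(0, row1 - (n - col1)), min(row1, col1)
    return sum(p for x in range(lo, hi + 1)
               if (p := prob(x)) <= p_obs * (1 + 1e-12))


class TestTcEnrichment:
    def _ctx_with_t_minus1(self, n_t, n_other):
        counts = np.zeros((3, 4), dtype=int)
        counts[0, 3] = n_t  # position -1, base T
        counts[0, 0] = n_other
        counts[1, 1] = n_t + n_other  # the edited C column
        counts[2, 0] = n_t + n_other
        return gp.ContextMatrix(1, counts, n_rows=n_t + n_other)

    def test_null_case_or_near_one(self):
        res = gp.tc_enrichment(self._ctx_with_t_minus1(25, 75), 0.25,
                               background_n=100_000)
        assert 0.5 < res.odds_ratio < 2
        assert res.p_value > 0.05

    def test_matches_exact_enumeration_oracle(self):
        res = gp.tc_enrichment(self._ctx_with_t_minus1(70, 30), (25, 75))
        assert res.p_value == pytest.approx(
            fisher_two_sided_oracle([[70, 30], [25, 75]]), rel=1e-9
        )
        assert res.odds_ratio == pytest.approx((70 * 75) / (30 * 25))

    def test_zero_cell_continuity_corrected(self):
        res = gp.tc_enrichment(self._ctx_with_t_minus1(30, 0), (25, 75))
        assert res.continuity_corrected
        assert np.isfinite(res.odds_ratio) and res.odds_ratio > 0

    def test_no_contexts_raises(self):
        with pytest.raises(ValueError):
            gp.tc_enrichment(gp.ContextMatrix(1, np.zeros((3, 4), int), 0), 0.25)

    def test_genome_background_counts(self, toy_genome):
        t, other = gp.genome_tc_background(toy_genome)
        seq = toy_genome.contigs["chr1"]
        want_t = sum(
            1 for i in range(1, len(seq)) if seq[i] == "C" and seq[i - 1] == "T"
        ) + sum(
            1 for i in range(len(seq) - 1) if seq[i] == "G" and seq[i + 1] == "A"
        )
        assert t == want_t
        total_c = sum(1 for i in range(1, len(seq)) if seq[i] == "C") + sum(
            1 for i in range(len(seq) - 1) if seq[i] == "G"
        )
        assert t + other == total_c


class TestTTest:
    def test_identical_groups(self):
        res = gp.t_test_unpaired([1, 2, 3], [1, 2, 3])
        assert res.t == 0 and res.p == 1

    def test_matches_t_distribution_oracle(self):
        """p agrees with an independently computed t statistic and survival
        function on random instances, to 1e-10."""
        rng = np.random.default_rng(8)
        for _ in range(50):
            a = rng.normal(0, 1, size=int(rng.integers(2, 12)))
            b = rng.normal(rng.uniform(-2, 2), 1.5, size=int(rng.integers(2, 12)))
            res = gp.t_test_unpaired(a, b)
            na, nb = len(a), len(b)
            sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (
                na + nb - 2
            )
            t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
            p = 2 * sps.t.sf(abs(t), na + nb - 2)
            assert res.t == pytest.approx(t, abs=1e-12)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_shifted_group_significant(self):
        res = gp.t_test_unpaired([1, 2, 3], [11, 12, 13])
        assert res.p < 0.01
        assert res.df == 4

    def test_degenerate_zero_variance(self):
        res = gp.t_test_unpaired([0, 0], [0, 0])
        assert res.t == 0 and res.p == 1
        res = gp.t_test_unpaired([0, 0], [1, 1])
        assert res.degenerate == "infinite_t" and res.p == 0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            gp.t_test_unpaired([1], [1, 2])

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=10),
        st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=10),
    )
    def test_symmetry_property(self, a, b):
        """Swapping groups flips the sign of t and preserves p."""
        r1 = gp.t_test_unpaired(a, b)
        r2 = gp.t_test_unpaired(b, a)
        assert r1.p == pytest.approx(r2.p, rel=1e-9)
        assert r1.t == pytest.approx(-r2.t, rel=1e-9, abs=1e-12)
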