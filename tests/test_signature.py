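"""Count matrices, logo export, and Fisher-based enrichment tests."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from p53sig.signature import (
    BONFERRONI_M,
    ContingencyTable2x2,
    SignatureSpec,
    concurrent_enrichment,
    count_nucleotides,
    fisher_exact_two_tailed,
    position_enrichment,
    to_logo_matrix,
)
from p53sig.simulate import signature_base_probs, simulate_re_sets


def exact_fisher_oracle(a, b, c, d):
    """Exact rational enumeration of the two-tailed hypergeometric sum."""
    n1, m1 = a + b, a + c
    n2 = c + d
    n = n1 + n2
    denom = comb(n, m1)
    pmf = {
        k: Fraction(comb(n1, k) * comb(n2, m1 - k), denom)
        for k in range(max(0, m1 - n2), min(n1, m1) + 1)
    }
    obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= obs))


class TestCountNucleotides:
    def test_single_site_counted(self):
        m = count_nucleotides(["GGGCATGCCC" * 2])
        assert m.n == 1
        np.testing.assert_array_equal(m.counts[8], [0, 1, 0, 0])  # C at 9

    def test_empty_set_is_zero(self):
        m = count_nucleotides([])
        assert m.n == 0
        assert m.counts.sum() == 0

    def test_sampled_frequency_within_binomial_noise(self):
        probs = signature_base_probs(0.731, 0.731)
        sites, _, _ = simulate_re_sets(1000, 0, probs, probs, seed=5)
        m = count_nucleotides(sites)
        sd = np.sqrt(1000 * 0.731 * 0.269)
        assert abs(m.count(9, "C") - 731) <= 3 * sd

    def test_n_counts_toward_no_base(self):
        m = count_nucleotides(["N" + "A" * 19])
        assert m.counts[0].sum() == 0
        assert m.counts[1:].sum() == 19

    def test_wrong_length_reports_index(self):
        with pytest.raises(ValueError, match="site 1"):
            count_nucleotides(["A" * 20, "A" * 19])


class TestLogoMatrix:
    @pytest.mark.parametrize(
        "column_sites, expected_ic",
        [
            (["A" * 20, "A" * 20], 2.0),            # pure column
            (["A" * 20, "C" * 20, "G" * 20, "T" * 20], 0.0),  # uniform
            (["A" * 20, "C" * 20], 1.0),             # half/half
        ],
    )
    def test_information_content(self, column_sites, expected_ic):
        df = to_logo_matrix(count_nucleotides(column_sites))
        assert df["info_bits"].iloc[0] == pytest.approx(expected_ic)

    def test_frequencies_sum_to_one(self):
        probs = signature_base_probs(0.7, 0.6, 0.04)
        sites, _, _ = simulate_re_sets(50, 0, probs, probs, seed=3)
        df = to_logo_matrix(count_nucleotides(sites))
        np.testing.assert_allclose(df[list("ACGT")].sum(axis=1), 1.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            to_logo_matrix(count_nucleotides([]))


class TestFisherExact:
    def test_balanced_table_is_one(self):
        assert fisher_exact_two_tailed(ContingencyTable2x2(1, 1, 1, 1)) == 1.0

    def test_small_table_matches_hand_enumeration(self):
        # margins (4,4;4,4): p = 34/70 by summing P(a=0,1,3,4) + P(obs)
        p = fisher_exact_two_tailed(ContingencyTable2x2(3, 1, 1, 3))
        assert p == pytest.approx(34 / 70, rel=1e-9)

    @pytest.mark.parametrize(
        "table, printed_p",
        [
            ((152, 56, 738, 552), 1.30e-5),
            ((152, 56, 722, 568), 2.38e-6),
            ((121, 87, 541, 749), 1.63e-5),
        ],
    )
    def test_large_tables_match_scipy(self, table, printed_p):
        p = fisher_exact_two_tailed(ContingencyTable2x2(*table))
        _, p_scipy = stats.fisher_exact(np.array(table).reshape(2, 2))
        assert p == pytest.approx(p_scipy, rel=1e-7)
        assert p == pytest.approx(printed_p, rel=5e-3)

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    def test_symmetry_under_row_and_column_swaps(self, a, b, c, d):
        t = (a, b, c, d)
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            with pytest.raises(ValueError):
                fisher_exact_two_tailed(ContingencyTable2x2(*t))
            return
        p = fisher_exact_two_tailed(ContingencyTable2x2(a, b, c, d))
        for swapped in [(c, d, a, b), (b, a, d, c)]:
            assert fisher_exact_two_tailed(
                ContingencyTable2x2(*swapped)
            ) == pytest.approx(p, rel=1e-9)

    @given(
        a=st.integers(0, 10), b=st.integers(0, 10),
        c=st.integers(0, 10), d=st.integers(0, 10),
    )
    def test_matches_exact_enumeration(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        p = fisher_exact_two_tailed(ContingencyTable2x2(a, b, c, d))
        assert p == pytest.approx(exact_fisher_oracle(a, b, c, d), abs=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_tailed(ContingencyTable2x2(0, 0, 5, 5))
        with pytest.raises(ValueError):
            fisher_exact_two_tailed(ContingencyTable2x2(0, 5, 0, 5))


class TestPositionEnrichment:
    def test_identical_sets_are_flat(self):
        probs = signature_base_probs(0.7, 0.6, 0.04)
        sites, _, _ = simulate_re_sets(100, 0, probs, probs, seed=9)
        m = count_nucleotides(sites)
        records = position_enrichment(m, m)
        assert len(records) == 80
        for r in records:
            assert r.fold == pytest.approx(1.0)
            assert r.p == pytest.approx(1.0)

    def test_paper_scale_c9_record(self):
        # build matrices that reproduce the printed C9 table at (9, C)
        counts_a = np.zeros((20, 4), dtype=int)
        counts_b = np.zeros((20, 4), dtype=int)
        counts_a[:, 0] = 208
        counts_b[:, 0] = 1290
        counts_a[8] = [56, 152, 0, 0]
        counts_b[8] = [552, 738, 0, 0]
        records = position_enrichment(_matrix(counts_a, 208), _matrix(counts_b, 1290))
        rec = {(r.position, r.base): r for r in records}[(9, "C")]
        assert rec.fold == pytest.approx(1.28, abs=0.005)
        assert rec.p == pytest.approx(1.30e-5, rel=5e-3)
        assert rec.p_bonf == pytest.approx(min(1.0, 80 * rec.p))
        assert rec.p_bonf > rec.p

    def test_bonferroni_bounds(self):
        probs = signature_base_probs(0.8, 0.5, 0.04)
        sa, sb, _ = simulate_re_sets(150, 400, probs, probs, seed=21)
        records = position_enrichment(
            count_nucleotides(sa), count_nucleotides(sb)
        )
        for r in records:
            assert r.p <= r.p_bonf <= 1.0

    def test_planted_effect_detected_only_at_planted_position(self):
        # single perturbed position: C9 boosted in set A
        detections = []
        for seed in range(20):
            pa = signature_base_probs(0.85, 0.5, 0.04)
            pb = signature_base_probs(0.5, 0.5, 0.04)
            sa, sb, _ = simulate_re_sets(1000, 1000, pa, pb, seed=seed)
            recs = position_enrichment(
                count_nucleotides(sa), count_nucleotides(sb)
            )
            flagged = {r.position for r in recs if r.p < 0.05 / 80}
            detections.append(9 in flagged)
        assert sum(detections) > 10

    def test_degenerate_markers(self):
        counts_a = np.zeros((20, 4), dtype=int)
        counts_b = np.zeros((20, 4), dtype=int)
        counts_a[:, 0] = 10
        counts_b[:, 0] = 10
        counts_a[5] = [5, 5, 0, 0]
        counts_b[5] = [10, 0, 0, 0]
        records = position_enrichment(_matrix(counts_a, 10), _matrix(counts_b, 10))
        rec = {(r.position, r.base): r for r in records}
        assert rec[(6, "C")].degenerate and rec[(6, "C")].fold == np.inf
        assert rec[(6, "G")].degenerate and rec[(6, "G")].fold == 1.0


class TestConcurrentEnrichment:
    def test_paper_counts_reproduced_from_sites(self):
        # synthesise site lists realising the printed concurrent table
        def sites(n_with, n_total):
            with_sig = "AAACAAGCCCAGACAAGCCC"
            without = "AAACAAGCTCAAACAAGCCC"  # T9, A12
            return [with_sig] * n_with + [without] * (n_total - n_with)

        spec = SignatureSpec(((9, "C"), (12, "G")))
        rec = concurrent_enrichment(sites(121, 208), sites(541, 1290), spec)
        assert rec.table.a == 121 and rec.table.c == 541
        assert rec.fold == pytest.approx(1.39, abs=0.005)
        assert rec.p == pytest.approx(1.63e-5, rel=5e-3)

    def test_no_matching_site_is_degenerate(self):
        spec = SignatureSpec(((1, "G"),))
        rec = concurrent_enrichment(["A" * 20] * 5, ["A" * 20] * 5, spec)
        assert rec.degenerate

    def test_single_pair_spec_consistent_with_positionwise(self):
        probs = signature_base_probs(0.7, 0.6, 0.04)
        sa, sb, _ = simulate_re_sets(120, 300, probs, probs, seed=31)
        spec = SignatureSpec(((9, "C"),))
        rec = concurrent_enrichment(sa, sb, spec, bonferroni_m=BONFERRONI_M)
        pos = {
            (r.position, r.base): r
            for r in position_enrichment(
                count_nucleotides(sa), count_nucleotides(sb)
            )
        }[(9, "C")]
        assert rec.table == pos.table
        assert rec.p == pytest.approx(pos.p)
        assert rec.fold == pytest.approx(pos.fold)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SignatureSpec(())
        with pytest.raises(ValueError):
            SignatureSpec(((9, "C"), (9, "T")))
        with pytest.raises(ValueError):
            SignatureSpec(((21, "C"),))


def _matrix(counts, n):
    from p53sig.signature import NucleotideCountMatrix

    return NucleotideCountMatrix(counts, n=n)
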