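"""APOBEC signature calling, motif counting, Fisher/BH, and spectra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import bh_step_up, fisher_two_sided_enumeration
from apobecsig.catalog_io import Mutation
from apobecsig.enrichment import (
    ContextCounts,
    EnrichmentResult,
    SPECTRUM_CHANNELS,
    benjamini_hochberg,
    classify_cohort,
    classify_substitution,
    count_motifs_in_windows,
    enrich_sample,
    fisher_enrichment_test,
    minimum_apobec_estimate,
    trinucleotide_spectrum,
)

RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def mut(ctx: str, alt: str, pos: int = 100, sample: str = "S") -> Mutation:
    ref = ctx[len(ctx) // 2]
    return Mutation("chr1", pos, ref, alt, sample, context=ctx)


class TestClassifySubstitution:
    def test_exhaustive_truth_table(self):
        """Agreement with an independently enumerated TCW/WGA definition."""
        expected = set()
        # plus-strand TCW: T C (A|T), alt T or G
        for three in "AT":
            for alt in "TG":
                expected.add(("T", "C", alt, three))
        # reverse-complement events: WGA center G
        for five, ref, alt, three in list(expected):
            expected.add((RC[three], RC[ref], RC[alt], RC[five]))
        for five in "ACGT":
            for ref in "ACGT":
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    for three in "ACGT":
                        m = mut(f"{five}{ref}{three}", alt)
                        assert classify_substitution(m) == (
                            (five, ref, alt, three) in expected
                        ), (five, ref, alt, three)

    @pytest.mark.parametrize(
        "ctx,alt,expected",
        [
            ("TCA", "T", True),    # TCW -> TTW
            ("TCT", "G", True),    # TCW -> TGW
            ("TCC", "T", False),   # W excludes C
            ("TGA", "A", True),    # WGA -> WAA (complementary strand)
            ("TCA", "A", False),   # only T/G alternates are the signature
            ("NCA", "T", False),   # N flank is uncallable
        ],
    )
    def test_quoted_cases(self, ctx, alt, expected):
        assert classify_substitution(mut(ctx, alt)) is expected

    def test_no_context_is_uncallable(self):
        assert classify_substitution(Mutation("chr1", 1, "C", "T", "S")) is False


class TestCountMotifs:
    """The mutated position itself is excluded from availability counting."""

    @pytest.mark.parametrize(
        "ctx,alt,n_tcw,n_c",
        [
            # center C is the mutated base: its TCA motif and its C do not count
            ("TTCAT", "T", 0, 0),
            ("GTCAC", "T", 0, 2),
            # center A mutated: the TCA centered on the flanking C does count
            ("TCAGG", "T", 1, 3),
            ("AAAAA", "C", 0, 0),
        ],
    )
    def test_hand_counted_windows(self, ctx, alt, n_tcw, n_c):
        counts = count_motifs_in_windows([mut(ctx, alt)])
        assert (counts.n_tcw, counts.n_c) == (n_tcw, n_c)

    def test_both_strand_motifs_counted(self):
        # window: ..TCA..TGA.. with mutated center elsewhere
        ctx = "TCAT" + "A" + "TGAA"  # length 9, center idx 4 = 'A'
        counts = count_motifs_in_windows([mut(ctx, "G")])
        # TCA centered idx1 (C), TGA centered idx6 (G); C bases: idx1; G: idx6
        assert counts == ContextCounts(n_tcw=2, n_c=2)

    def test_windows_are_a_multiset(self):
        m = mut("TCAGG", "T")
        one = count_motifs_in_windows([m])
        two = count_motifs_in_windows([m, m])
        assert (two.n_tcw, two.n_c) == (2 * one.n_tcw, 2 * one.n_c)

    def test_collapsed_union_counts_overlaps_once(self, sim_reference):
        reference, sites = sim_reference
        chrom = next(iter(reference.keys()))
        # two nearby mutations with heavily overlapping windows
        p1, p2 = 5000, 5010
        muts = []
        for p in (p1, p2):
            ref = reference.base(chrom, p)
            alt = "A" if ref != "A" else "G"
            muts.append(
                Mutation(chrom, p, ref, alt, "S", context=reference.fetch(chrom, p - 20, p + 20))
            )
        multi = count_motifs_in_windows(muts)
        collapsed = count_motifs_in_windows(muts, collapse=True, reference=reference)
        assert collapsed.n_c < multi.n_c
        assert collapsed.n_tcw <= multi.n_tcw

    def test_missing_context_raises(self):
        with pytest.raises(ValueError):
            count_motifs_in_windows([Mutation("chr1", 1, "C", "T", "S")])


class TestFisher:
    def test_odds_ratio_arithmetic(self):
        odds, _ = fisher_enrichment_test(10, 10, ContextCounts(100, 900))
        assert odds == pytest.approx(9.0)

    def test_zero_numerator_gives_zero_odds(self):
        odds, p = fisher_enrichment_test(0, 50, ContextCounts(10, 90))
        assert odds == 0.0
        assert p == pytest.approx(fisher_two_sided_enumeration(0, 50, 10, 90), abs=1e-10)

    def test_zero_denominator_gives_infinite_odds(self):
        odds, _ = fisher_enrichment_test(5, 0, ContextCounts(10, 90))
        assert math.isinf(odds)

    def test_identical_proportions_give_p_one(self):
        _, p = fisher_enrichment_test(5, 10, ContextCounts(10, 20))
        assert p == pytest.approx(1.0)

    def test_all_zero_cells_error(self):
        with pytest.raises(ValueError):
            fisher_enrichment_test(0, 0, ContextCounts(0, 0))

    def test_matches_hypergeometric_enumeration(self):
        """Spot-check against the exact-rational enumeration oracle."""
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 100:
            a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            _, p = fisher_enrichment_test(a, b, ContextCounts(c, d))
            assert p == pytest.approx(fisher_two_sided_enumeration(a, b, c, d), abs=1e-10)
            checked += 1


class TestBenjaminiHochberg:
    def test_step_up_by_hand(self):
        assert benjamini_hochberg([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.3]) == pytest.approx([0.3])

    def test_all_ones_stay_ones(self):
        assert benjamini_hochberg([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_step_up_oracle(self, ps):
        assert benjamini_hochberg(ps) == pytest.approx(bh_step_up(ps), abs=1e-12)


def _result(sample, p, odds):
    return EnrichmentResult(sample_id=sample, n_apobec=10, n_other=10,
                            n_tcw=100, n_c=900, odds_ratio=odds, p_value=p)


class TestClassification:
    def test_thresholds_are_strict(self):
        # single-sample cohorts so q == p exactly
        called = classify_cohort([_result("a", 0.04, 2.5)])[0]
        assert called.is_apobec_mutated
        on_or_boundary = classify_cohort([_result("b", 0.04, 2.0)])[0]
        assert not on_or_boundary.is_apobec_mutated
        on_q_boundary = classify_cohort([_result("c", 0.05, 10.0)])[0]
        assert not on_q_boundary.is_apobec_mutated

    def test_q_values_dominate_p(self):
        results = classify_cohort([_result(f"s{i}", p, 3.0) for i, p in
                                   enumerate([0.001, 0.01, 0.04, 0.2])])
        for r in results:
            assert r.q_value >= r.p_value

    def test_empty_cohort(self):
        assert classify_cohort([]) == []


class TestMinimumEstimate:
    def test_excess_over_context_expectation(self):
        r = _result("s", 1e-6, 9.0)
        r.is_apobec_mutated = True
        assert minimum_apobec_estimate(r) == pytest.approx(10 - 10 * (100 / 900))

    def test_zero_when_not_called(self):
        assert minimum_apobec_estimate(_result("s", 0.5, 9.0)) == 0.0

    def test_zero_apobec_count_gives_zero(self):
        r = EnrichmentResult("s", 0, 20, 100, 900, 0.0, 1.0)
        r.is_apobec_mutated = True
        assert minimum_apobec_estimate(r) == 0.0

    def test_degenerate_context_error(self):
        r = EnrichmentResult("s", 5, 5, 0, 0, math.inf, 0.01)
        r.is_apobec_mutated = True
        with pytest.raises(ValueError):
            minimum_apobec_estimate(r)

    def test_never_exceeds_apobec_count(self):
        r = EnrichmentResult("s", 7, 0, 1, 900, math.inf, 1e-9)
        r.is_apobec_mutated = True
        assert minimum_apobec_estimate(r) <= 7


class TestSpectrum:
    def test_purine_reference_reverse_complemented(self):
        # plus-strand TGC with G>A maps to the pyrimidine channel G[C>T]A
        spec = trinucleotide_spectrum([mut("TGC", "A")])
        assert spec["G[C>T]A"] == 1
        assert spec.sum() == 1

    def test_empty_input_all_zero(self):
        spec = trinucleotide_spectrum([])
        assert spec.sum() == 0
        assert len(spec) == 96 == len(SPECTRUM_CHANNELS)

    def test_sum_equals_callable_mutations(self):
        muts = [mut("TCA", "T"), mut("NCA", "T"), mut("ACG", "T"), mut("TGA", "C")]
        spec = trinucleotide_spectrum(muts)
        assert spec.sum() == 3  # the N-flanked mutation is excluded


def test_enrich_sample_counts_reconcile(sim_reference):
    reference, sites = sim_reference
    from apobecsig.simulate import CatalogSimConfig, simulate_catalog

    cfg = CatalogSimConfig(n_mutations=200, apobec_fraction=0.3, seed=3)
    catalog, _ = simulate_catalog(reference, sites, cfg)
    res = enrich_sample("S1", catalog.mutations_for("S1"))
    assert res.n_apobec + res.n_other == 200
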