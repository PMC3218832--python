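"""Summit-window personalization, binding potential and pair classification."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from emsaseq.allele_binding import (
    DIRECT_POSITIVE,
    NO_CORRELATION,
    NO_DIFFERENCE,
    BindingRegionSummit,
    PairComparison,
    Variant,
    aggregate,
    binding_potential,
    compare_pair,
    hypergeometric_enrichment,
    individual_potential,
    map_tas,
    personalize_sequence,
    scan_window,
    tas_category_test,
    window_bounds,
)
from emsaseq.kmer_counting import canonical, revcomp

from .conftest import random_kmers


def make_brs(ref_window, heights, variants=None, brs_id="BRS000", summit=1000):
    return BindingRegionSummit(
        brs_id=brs_id,
        chrom="chrT",
        br_start=summit - 300,
        br_end=summit + 300,
        summit=summit,
        ref_window=ref_window,
        heights=heights,
        variants=variants or {},
    )


@pytest.fixture
def window(rng):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])


class TestWindowBounds:
    def test_exact_300_centered(self):
        start, end = window_bounds(1000)
        assert (start, end) == (850, 1150)
        assert end - start == 300

    def test_summit_at_offset_150(self):
        start, _ = window_bounds(1234)
        assert 1234 - start == 150


class TestPersonalizeSequence:
    def test_no_variants_identity(self, window):
        assert personalize_sequence(window, []) == [window]

    def test_hom_alt_single_substitution(self, window):
        alt = "A" if window[42] != "A" else "C"
        v = Variant(pos=42, ref=window[42], alt=alt, genotype=(1, 1))
        out = personalize_sequence(window, [v])
        assert len(out) == 1
        diffs = [i for i, (a, b) in enumerate(zip(window, out[0])) if a != b]
        assert diffs == [42]
        assert out[0][42] == alt

    def test_two_unphased_hets_expand_to_two_haplotypes(self, window):
        alts = {}
        variants = []
        for pos in (10, 250):
            alt = "A" if window[pos] != "A" else "G"
            alts[pos] = alt
            variants.append(
                Variant(pos=pos, ref=window[pos], alt=alt, genotype=(0, 1))
            )
        out = personalize_sequence(window, variants)
        assert len(out) == 2
        # policy: first haplotype all-reference, second all-alternate
        assert out[0] == window
        expected = list(window)
        for pos, alt in alts.items():
            expected[pos] = alt
        assert out[1] == "".join(expected)

    def test_ref_mismatch_names_position(self, window):
        wrong = "A" if window[5] != "A" else "C"
        v = Variant(pos=5, ref=wrong, alt="T", genotype=(1, 1))
        with pytest.raises(ValueError, match="position 5"):
            personalize_sequence(window, [v])

    def test_indel_rejected(self):
        with pytest.raises(ValueError, match="indel"):
            Variant(pos=0, ref="A", alt="AT", genotype=(0, 1))

    def test_out_of_window_position_rejected(self, window):
        v = Variant(pos=300, ref="A", alt="C", genotype=(1, 1))
        with pytest.raises(ValueError, match="outside"):
            personalize_sequence(window, [v])


class TestScanAndPotential:
    def test_no_enriched_kmers_empty(self, window):
        assert scan_window(window, {}) == []
        assert binding_potential([]) == 0.0

    def test_single_exact_hit(self):
        kmer = "ACGTACGTACG"
        hits = scan_window(kmer, {canonical(kmer): 5.0})
        assert hits == [(0, canonical(kmer), 5.0)]
        assert binding_potential(hits) == 5.0

    def test_overlapping_hits_sum_matches_sliding_oracle(self, rng, window):
        affinity = {}
        for m in random_kmers(rng, 30, 11):
            affinity[canonical(m)] = float(rng.uniform(1, 10))
        # plant three affinity k-mers at overlapping offsets
        planted = list(affinity)[:3]
        seq = list(window)
        for off, m in zip((40, 45, 120), planted):
            seq[off : off + 11] = m
        seq = "".join(seq)
        hits = scan_window(seq, affinity)
        # independent sliding-window oracle
        expected = sum(
            affinity.get(canonical(seq[i : i + 11]), 0.0)
            for i in range(len(seq) - 10)
        )
        assert binding_potential(hits) == pytest.approx(expected)
        assert {m for _, m, _ in hits} >= {canonical(m) for m in planted[2:]}

    def test_reverse_complement_window_invariance(self, rng, window):
        affinity = {canonical(m): 2.0 for m in random_kmers(rng, 200, 11)}
        fwd = binding_potential(scan_window(window, affinity))
        rc = binding_potential(scan_window(revcomp(window), affinity))
        assert fwd == pytest.approx(rc)

    def test_variant_outside_enriched_kmers_leaves_b_unchanged(self, rng, window):
        kmer = "GGGAAATTCCC"
        seq = window[:100] + kmer + window[111:]
        affinity = {canonical(kmer): 4.0}
        brs = make_brs(seq, {"a": 1.0, "b": 2.0})
        b_ref = individual_potential(brs, "a", affinity)
        # a SNP far from the planted binder
        alt = "A" if seq[250] != "A" else "C"
        brs.variants["b"] = [Variant(250, seq[250], alt, (1, 1))]
        assert individual_potential(brs, "b", affinity) == pytest.approx(b_ref)

    def test_het_potential_is_haplotype_mean(self, window):
        kmer = "GGGAAATTCCC"
        seq = window[:100] + kmer + window[111:]
        affinity = {canonical(kmer): 6.0}
        # het SNP destroying the binder on the alt haplotype
        alt = "G" if kmer[5] != "G" else "T"
        brs = make_brs(seq, {"a": 1.0})
        brs.variants["a"] = [Variant(105, kmer[5], alt, (0, 1))]
        b_hom = binding_potential(scan_window(seq, affinity))
        got = individual_potential(brs, "a", affinity)
        assert got == pytest.approx(b_hom / 2.0)


class TestComparePair:
    def affinity(self):
        return {"RELAp50": {canonical("GGGAAATTCCC"): 6.0}}

    def test_identical_sequences_no_difference(self, window):
        brs = make_brs(window, {"a": 5.0, "b": 1.0})
        cmp = compare_pair(brs, "a", "b", self.affinity())
        assert cmp.cls == NO_DIFFERENCE
        assert cmp.b_a == cmp.b_b

    def brs_with_binder_loss(self, window, heights):
        kmer = "GGGAAATTCCC"
        seq = window[:100] + kmer + window[111:]
        alt = "G" if kmer[5] != "G" else "T"
        brs = make_brs(seq, heights)
        brs.variants["b"] = [Variant(105, kmer[5], alt, (1, 1))]
        return brs

    def test_direct_positive(self, window):
        brs = self.brs_with_binder_loss(window, {"a": 5.0, "b": 1.0})
        cmp = compare_pair(brs, "a", "b", self.affinity())
        assert cmp.b_a > cmp.b_b and cmp.delta_invivo > 0
        assert cmp.cls == DIRECT_POSITIVE

    def test_no_correlation(self, window):
        brs = self.brs_with_binder_loss(window, {"a": 1.0, "b": 5.0})
        cmp = compare_pair(brs, "a", "b", self.affinity())
        assert cmp.b_a > cmp.b_b and cmp.delta_invivo < 0
        assert cmp.cls == NO_CORRELATION

    def test_per_dimer_fallback_stops_at_first_success(self, window):
        kmer = "GGGAAATTCCC"
        seq = window[:100] + kmer + window[111:]
        alt = "G" if kmer[5] != "G" else "T"
        brs = make_brs(seq, {"a": 5.0, "b": 1.0})
        brs.variants["b"] = [Variant(105, kmer[5], alt, (1, 1))]
        affinities = {
            "empty_dimer": {},  # sees no difference
            "live_dimer": {canonical(kmer): 6.0},
        }
        cmp = compare_pair(
            brs, "a", "b", affinities,
            method="per_dimer_fallback",
            dimer_order=("empty_dimer", "live_dimer"),
        )
        assert cmp.dimer == "live_dimer"
        assert cmp.cls == DIRECT_POSITIVE

    def test_per_dimer_fallback_reports_last_tried(self, window):
        brs = make_brs(window, {"a": 5.0, "b": 1.0})
        cmp = compare_pair(
            brs, "a", "b", {"d1": {}, "d2": {}},
            method="per_dimer_fallback", dimer_order=("d1", "d2"),
        )
        assert cmp.dimer == "d2"
        assert cmp.cls == NO_DIFFERENCE

    def test_missing_height_is_error(self, window):
        brs = make_brs(window, {"a": 1.0})
        with pytest.raises(KeyError, match="no peak height"):
            compare_pair(brs, "a", "zz", self.affinity())


class TestAggregate:
    def comparison(self, brs_id, cls):
        return PairComparison(
            brs_id=brs_id, individuals=("a", "b"), delta_invivo=0.0,
            b_a=0.0, b_b=0.0, method="summed_dimers", dimer=None, cls=cls,
        )

    def test_all_no_difference(self):
        agg = aggregate([self.comparison("x", NO_DIFFERENCE)] * 3)
        assert agg["classes"][NO_DIFFERENCE]["fraction"] == 1.0
        assert agg["classes"][DIRECT_POSITIVE]["count"] == 0

    def test_mixed_toy_set_matches_hand_tally(self):
        comps = (
            [self.comparison("b1", DIRECT_POSITIVE)] * 5
            + [self.comparison("b2", DIRECT_POSITIVE)] * 1
            + [self.comparison("b2", NO_CORRELATION)] * 3
            + [self.comparison("b3", NO_DIFFERENCE)] * 1
        )
        agg = aggregate(comps)
        assert agg["n_comparisons"] == 10
        assert agg["classes"][DIRECT_POSITIVE] == {
            "count": 6, "fraction": 0.6, "n_brs": 2,
        }
        assert agg["classes"][NO_CORRELATION]["count"] == 3
        assert agg["direct_positive_given_difference"] == pytest.approx(6 / 9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])


class TestMapTas:
    def brs_at(self, summit, brs_id, window):
        return make_brs(window, {"a": 1.0}, brs_id=brs_id, summit=summit)

    def test_tas_at_summit_distance_zero(self, window):
        brs = self.brs_at(5000, "B0", window)
        tas = pd.DataFrame({"tas_id": ["rs1"], "chrom": ["chrT"], "pos": [5000]})
        mapped = map_tas(tas, [brs])
        assert mapped.loc[0, "distance"] == 0
        assert bool(mapped.loc[0, "within_limit"])

    def test_tie_resolves_to_lower_coordinate(self, window):
        brs_list = [self.brs_at(4000, "LOW", window), self.brs_at(6000, "HIGH", window)]
        tas = pd.DataFrame({"tas_id": ["rs1"], "chrom": ["chrT"], "pos": [5000]})
        mapped = map_tas(tas, brs_list)
        assert mapped.loc[0, "nearest_brs"] == "LOW"

    def test_limit_flag_and_ordering(self, window):
        brs = self.brs_at(5000, "B0", window)
        tas = pd.DataFrame(
            {
                "tas_id": ["far", "near"],
                "chrom": ["chrT", "chrT"],
                "pos": [9000, 5100],
            }
        )
        mapped = map_tas(tas, [brs], limit=1000)
        assert list(mapped["tas_id"]) == ["near", "far"]
        assert list(mapped["within_limit"]) == [True, False]

    def test_empty_brs_list_rejected(self):
        tas = pd.DataFrame({"tas_id": ["rs1"], "chrom": ["chrT"], "pos": [1]})
        with pytest.raises(ValueError, match="empty"):
            map_tas(tas, [])


class TestHypergeometric:
    def test_zero_observed_gives_one(self):
        assert hypergeometric_enrichment(20, 5, 10, 0) == pytest.approx(1.0)

    def test_matches_exact_combinatorial_oracle(self):
        # P(X >= 5) for N=20, K=5, n=10 by direct summation
        N, K, n = 20, 5, 10
        expected = sum(
            comb(K, i) * comb(N - K, n - i) for i in range(5, min(K, n) + 1)
        ) / comb(N, n)
        assert hypergeometric_enrichment(N, K, n, 5) == pytest.approx(
            expected, rel=1e-12
        )

    def test_category_test_counts(self, window):
        brs = make_brs(window, {"a": 1.0}, summit=5000)
        tas = pd.DataFrame(
            {
                "tas_id": [f"rs{i}" for i in range(6)],
                "chrom": ["chrT"] * 6,
                "pos": [5000, 5100, 5200, 90_000, 91_000, 92_000],
                "category": ["auto", "auto", "other", "auto", "other", "other"],
            }
        )
        mapped = map_tas(tas, [brs], limit=1000)
        result = tas_category_test(mapped, "auto")
        assert (result["N"], result["K"], result["n"], result["k"]) == (6, 3, 3, 2)
        expected = sum(
            comb(3, i) * comb(3, 3 - i) for i in range(2, 4)
        ) / comb(6, 3)
        assert result["p"] == pytest.approx(expected, rel=1e-12)
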