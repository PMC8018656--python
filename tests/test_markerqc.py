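"""Marker validation statistics: frequencies, PIC/PID, exclusion, HWE, LD,
genotype accumulation."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as hst

from bonecheck.genodata import StrGenotype
from bonecheck.markerqc import (
    allele_frequencies,
    cumulative_pid,
    exclusion_probabilities,
    exclusion_probabilities_enum,
    genotype_accumulation,
    genotype_counts,
    hwe_exact,
    ld_permutation,
    locus_stats,
    panel_summary,
)


def _equifrequent_cohort(k, locus="L"):
    """All k*k ordered pairs as individuals -> exact equifrequent alleles."""
    return [
        StrGenotype({locus: (i + 1, j + 1)}) for i in range(k) for j in range(k)
    ]


class TestFrequenciesAndStats:
    def test_hand_counted_frequencies(self):
        genos = [
            StrGenotype({"L": (1, 1)}),
            StrGenotype({"L": (1, 2)}),
            StrGenotype({"L": (2, 3)}),
        ]
        freqs = allele_frequencies(genos, "L")
        assert freqs[1] == pytest.approx(0.5)
        assert freqs[2] == pytest.approx(1 / 3)
        assert freqs[3] == pytest.approx(1 / 6)

    def test_all_homozygous(self):
        genos = [StrGenotype({"L": (5, 5)})] * 3
        assert allele_frequencies(genos, "L") == {5: 1.0}

    def test_missing_excluded(self):
        genos = [StrGenotype({"L": (1, 2)}), StrGenotype({"L": (0, 0)})]
        assert allele_frequencies(genos, "L") == {1: 0.5, 2: 0.5}
        with pytest.raises(ValueError):
            allele_frequencies([StrGenotype({"L": (0, 0)})], "L")

    @pytest.mark.parametrize("k", range(2, 11))
    def test_equifrequent_closed_forms(self, k):
        s = locus_stats(_equifrequent_cohort(k), "L")
        assert s.PID == pytest.approx((2 * k - 1) / k**3, abs=1e-12)
        p = 1.0 / k
        pic_expected = s.H_E - math.comb(k, 2) * 2 * p**2 * p**2
        assert s.PIC == pytest.approx(pic_expected, abs=1e-12)
        assert s.H_E == pytest.approx(1 - 1 / k, abs=1e-12)
        assert s.A_e == pytest.approx(k, abs=1e-9)

    def test_monomorphic_locus(self):
        s = locus_stats([StrGenotype({"L": (7, 7)})] * 4, "L")
        assert (s.A_n, s.A_e, s.H_O, s.H_E, s.PIC, s.PID) == (1, 1.0, 0.0, 0.0, 0.0, 1.0)
        assert s.monomorphic
        assert s.null_freq == 0.0

    def test_invariants_on_random_cohorts(self, panels):
        lion, _, _ = panels
        from bonecheck.synth import sample_genotype

        rng = np.random.default_rng(3)
        genos = [sample_genotype(lion, rng) for _ in range(60)]
        for locus in lion.loci[:6]:
            s = locus_stats(genos, locus)
            assert s.PIC <= s.H_E + 1e-12
            assert s.A_e <= s.A_n + 1e-9
            for v in (s.H_O, s.H_E, s.PIC, s.PID, s.Pe1, s.Pe2):
                assert -1e-12 <= v <= 1 + 1e-12

    @given(hst.permutations(list(range(1, 7))))
    def test_statistics_invariant_under_allele_relabeling(self, perm):
        genos = [
            StrGenotype({"L": (1, 2)}),
            StrGenotype({"L": (2, 3)}),
            StrGenotype({"L": (4, 4)}),
            StrGenotype({"L": (5, 6)}),
            StrGenotype({"L": (1, 1)}),
        ]
        mapping = {i + 1: perm[i] for i in range(6)}
        relabeled = [
            StrGenotype({"L": (mapping[a], mapping[b])})
            for (a, b) in (g.pair("L") for g in genos)
        ]
        a = locus_stats(genos, "L")
        b = locus_stats(relabeled, "L")
        for f in ("A_n", "A_e", "H_O", "H_E", "PIC", "PID", "Pe1", "Pe2", "null_freq"):
            assert getattr(a, f) == pytest.approx(getattr(b, f), abs=1e-12)

    def test_cumulative_pid_is_product(self):
        s1 = locus_stats(_equifrequent_cohort(2), "L")
        assert cumulative_pid([s1]) == s1.PID
        assert cumulative_pid([s1, s1]) == pytest.approx(0.375**2)
        with pytest.raises(ValueError):
            cumulative_pid([])

    def test_panel_summary_shape(self, ref_panels):
        lion_ref, _ = ref_panels
        df = panel_summary(lion_ref)
        assert len(df) == len(lion_ref[0].loci)
        assert {"PID", "PIC", "H_E", "Pe1", "Pe2"} <= set(df.columns)


class TestExclusionProbabilities:
    @pytest.mark.parametrize("k", [2, 3, 5, 8, 10])
    def test_closed_form_matches_enumeration(self, k):
        rng = np.random.default_rng(k)
        for _ in range(3):
            p = rng.dirichlet(np.ones(k))
            c1, c2 = exclusion_probabilities(p)
            e1, e2 = exclusion_probabilities_enum(p)
            assert c1 == pytest.approx(e1, abs=1e-12)
            assert c2 == pytest.approx(e2, abs=1e-12)

    def test_monomorphic_no_exclusion_power(self):
        pe1, pe2 = exclusion_probabilities(np.array([1.0]))
        assert pe1 == pytest.approx(0.0, abs=1e-12)
        assert pe2 == pytest.approx(0.0, abs=1e-12)


def _hwe_two_allele_oracle(nAA, nAB, nBB):
    """Independent exact-test oracle for two alleles via rational arithmetic:
    enumerate heterozygote counts compatible with the allele margins."""
    n = nAA + nAB + nBB
    mA, mB = 2 * nAA + nAB, 2 * nBB + nAB

    def cond_prob(a, h, b):
        return Fraction(
            math.factorial(n) * 2**h * math.factorial(mA) * math.factorial(mB),
            math.factorial(2 * n)
            * math.factorial(a)
            * math.factorial(h)
            * math.factorial(b),
        )

    obs = cond_prob(nAA, nAB, nBB)
    total = Fraction(0)
    for h in range(min(mA, mB) + 1):
        if (mA - h) % 2 or (mB - h) % 2:
            continue
        a, b = (mA - h) // 2, (mB - h) // 2
        if a < 0 or b < 0:
            continue
        q = cond_prob(a, h, b)
        if q <= obs:
            total += q
    return float(total)


class TestHweExact:
    def test_single_heterozygote_p_one(self):
        assert hwe_exact({(1, 2): 1}) == pytest.approx(1.0)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            hwe_exact({(1, 1): 5})

    @pytest.mark.parametrize(
        "counts",
        [
            {(1, 1): 3, (2, 2): 3},
            {(1, 1): 2, (1, 2): 6, (2, 2): 2},
            {(1, 1): 10, (1, 2): 1, (2, 2): 10},
            {(1, 2): 8, (1, 1): 1},
        ],
    )
    def test_enumeration_matches_rational_oracle(self, counts):
        nAA = counts.get((1, 1), 0)
        nAB = counts.get((1, 2), 0)
        nBB = counts.get((2, 2), 0)
        assert hwe_exact(counts) == pytest.approx(
            _hwe_two_allele_oracle(nAA, nAB, nBB), rel=1e-9
        )

    def test_monte_carlo_agrees_with_enumeration(self):
        counts = {(1, 1): 4, (1, 2): 2, (2, 2): 4, (1, 3): 2, (3, 3): 2}
        exact = hwe_exact(counts)
        reps = 20_000
        mc = hwe_exact(counts, mc_reps=reps, seed=5, enumeration_bound=0)
        se = math.sqrt(exact * (1 - exact) / reps)
        assert abs(mc - exact) < 3 * se + 2 / reps

    def test_monte_carlo_deterministic(self):
        counts = {(1, 1): 6, (1, 2): 3, (2, 2): 6}
        a = hwe_exact(counts, mc_reps=2000, seed=7, enumeration_bound=0)
        b = hwe_exact(counts, mc_reps=2000, seed=7, enumeration_bound=0)
        assert a == b


class TestLdPermutation:
    def _cohort(self, n=40, seed=0, copy=False):
        rng = np.random.default_rng(seed)
        genos = []
        for _ in range(n):
            a = tuple(sorted(rng.integers(1, 6, size=2)))
            b = a if copy else tuple(sorted(rng.integers(1, 6, size=2)))
            genos.append(StrGenotype({"A": a, "B": b}))
        return genos

    def test_perfectly_linked_loci_significant(self):
        genos = self._cohort(n=60, seed=1, copy=True)
        assert len({g.pair("A") for g in genos}) >= 10
        p = ld_permutation(genos, "A", "B", reps=199, seed=2)
        assert p <= 0.01

    def test_independent_loci_not_extreme(self):
        p = ld_permutation(self._cohort(n=60, seed=3), "A", "B", reps=199, seed=4)
        assert p > 0.01

    def test_deterministic_given_seed(self):
        genos = self._cohort(n=40, seed=5)
        p1 = ld_permutation(genos, "A", "B", reps=999, seed=9)
        p2 = ld_permutation(genos, "A", "B", reps=999, seed=9)
        assert p1 == p2

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError, match="reps"):
            ld_permutation(self._cohort(), "A", "B", reps=50, seed=0)


class TestGenotypeAccumulation:
    def test_single_individual_constant_one(self):
        genos = [StrGenotype({f"L{i}": (1, 2) for i in range(4)})]
        curve = genotype_accumulation(genos, n_reps=20, seed=0)
        assert (curve["mean_distinct"] == 1.0).all()

    def test_two_individuals_single_differing_locus(self):
        # hypergeometric: distinct count at subset size m is 1 + m/L in
        # expectation (the subset hits the one differing locus w.p. m/L)
        L = 6
        base = {f"L{i}": (1, 1) for i in range(L)}
        other = dict(base)
        other["L0"] = (2, 2)
        genos = [StrGenotype(base), StrGenotype(other)]
        curve = genotype_accumulation(genos, n_reps=4000, seed=1)
        for _, row in curve.iterrows():
            m = row["n_loci"]
            expected = 1 + m / L
            assert row["mean_distinct"] == pytest.approx(expected, abs=0.06)
        assert curve.iloc[-1]["mean_distinct"] == 2.0  # full panel always separates

    def test_missing_locus_is_wildcard(self):
        a = StrGenotype({"L0": (1, 2), "L1": (3, 4)})
        b = StrGenotype({"L0": (0, 0), "L1": (3, 4)})
        curve = genotype_accumulation([a, b], n_reps=50, seed=2)
        assert (curve["mean_distinct"] == 1.0).all()

    def test_cohort_fully_resolved_by_panel(self, ref_panels):
        lion_ref, _ = ref_panels
        curve = genotype_accumulation(lion_ref, n_reps=30, seed=3)
        assert curve.iloc[-1]["min_distinct"] == len(lion_ref)
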