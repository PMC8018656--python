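"""Relatedness, ESD outlier detection, matching and anomaly classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as hst
from scipy import stats as scipy_stats

from bonecheck.genodata import SampleRecord, Site, SnpAllele, SnpCallSet, StrGenotype
from bonecheck.match import (
    DuplicatePair,
    MatchClass,
    MatchParams,
    MatchResult,
    TagAbsentError,
    classify_anomalies,
    cohort_frequencies,
    esd_lambda,
    esd_outliers,
    find_duplicates,
    match_cohort,
    match_port_sample,
    qg_relatedness,
    relatedness_matrix,
)
from bonecheck.species import SpeciesAssignment, SpeciesCall, FinalCall
from bonecheck.synth import Sample, sample_genotype


def _blank_snp():
    return SnpCallSet({l: SnpAllele.UNDETERMINED for l in ("CR", "12S", "16S")})


def _sample(tag, genotype, facility="F01", site=Site.FARM, year=2018):
    rec = SampleRecord(f"{site.value}-{tag}", tag, facility, site, year)
    return Sample(rec, genotype, _blank_snp())


@hst.composite
def _freqs_and_genotype(draw):
    n_loci = draw(hst.integers(1, 4))
    freqs = {}
    genotype = {}
    for i in range(n_loci):
        k = draw(hst.integers(2, 6))
        weights = draw(
            hst.lists(hst.floats(0.05, 1.0), min_size=k, max_size=k)
        )
        total = sum(weights)
        freqs[f"L{i}"] = {j + 1: w / total for j, w in enumerate(weights)}
        a = draw(hst.integers(1, k))
        b = draw(hst.integers(1, k))
        genotype[f"L{i}"] = (a, b)
    return freqs, StrGenotype(genotype)


class TestQgRelatedness:
    @given(_freqs_and_genotype())
    def test_identity_gives_r_exactly_one(self, fg):
        freqs, g = fg
        assert qg_relatedness(g, StrGenotype(dict(g.alleles)), freqs) == 1.0

    def test_hand_worked_single_locus(self):
        freqs = {"L1": {1: 0.5, 2: 0.3, 3: 0.2}}
        x = StrGenotype({"L1": (1, 2)})
        y = StrGenotype({"L1": (1, 3)})
        # r_xy = -0.3/0.2 = -1.5, r_yx = -0.2/0.3; r = -13/12
        assert qg_relatedness(x, y, freqs) == pytest.approx(-13 / 12, abs=1e-12)

    @given(_freqs_and_genotype(), hst.integers(0, 2**31 - 1))
    def test_symmetric_by_construction(self, fg, seed):
        freqs, x = fg
        rng = np.random.default_rng(seed)
        y = StrGenotype(
            {
                l: tuple(int(a) for a in rng.choice(list(t.keys()), 2, p=list(t.values())))
                for l, t in freqs.items()
            }
        )
        assert qg_relatedness(x, y, freqs) == qg_relatedness(y, x, freqs)

    def test_matrix_agrees_with_scalar(self, panels):
        lion, _, _ = panels
        rng = np.random.default_rng(4)
        xs = [sample_genotype(lion, rng) for _ in range(6)]
        ys = [sample_genotype(lion, rng) for _ in range(5)]
        freqs = cohort_frequencies(xs + ys)
        mat = relatedness_matrix(xs, ys, freqs)
        for i, x in enumerate(xs):
            for j, y in enumerate(ys):
                assert mat[i, j] == pytest.approx(qg_relatedness(x, y, freqs), abs=1e-12)

    def test_unrelated_mean_near_zero(self, panels):
        lion, _, _ = panels
        rng = np.random.default_rng(5)
        xs = [sample_genotype(lion, rng) for _ in range(40)]
        ys = [sample_genotype(lion, rng) for _ in range(40)]
        mat = relatedness_matrix(xs, ys, {l: lion.freqs[l] for l in lion.loci})
        assert abs(float(np.mean(mat))) < 0.03

    def test_no_informative_loci_rejected(self):
        freqs = {"L1": {1: 1.0}}
        g = StrGenotype({"L1": (1, 1)})
        with pytest.raises(ValueError, match="informative"):
            qg_relatedness(g, g, freqs)

    def test_missing_loci_skipped(self):
        freqs = {"L1": {1: 0.5, 2: 0.3, 3: 0.2}, "L2": {1: 0.6, 2: 0.4}}
        x = StrGenotype({"L1": (1, 2), "L2": (0, 0)})
        y = StrGenotype({"L1": (1, 2), "L2": (1, 1)})
        # L2 missing in x, so only L1 contributes; identical pairs give r = 1
        assert qg_relatedness(x, y, freqs) == 1.0

    def test_degenerate_locus_skipped_entirely(self):
        # a heterozygote whose two equifrequent alleles exhaust the mass has
        # zero denominator in both directions: the locus carries no signal
        freqs = {"L1": {1: 0.5, 2: 0.5}}
        g = StrGenotype({"L1": (1, 2)})
        with pytest.raises(ValueError, match="informative"):
            qg_relatedness(g, g, freqs)


class TestEsd:
    def test_lambda_matches_direct_recomputation(self):
        for n, i, alpha in [(25, 1, 0.05), (101, 3, 0.05), (50, 5, 0.01)]:
            p = 1 - alpha / (2 * (n - i + 1))
            t = scipy_stats.t.ppf(p, n - i - 1)
            expected = (n - i) * t / np.sqrt((n - i - 1 + t * t) * (n - i + 1))
            assert esd_lambda(n, i, alpha) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_no_flags(self):
        assert esd_outliers(np.full(60, 3.7)).flagged == []

    def test_planted_outlier_flagged(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.standard_normal(100), [10.0]])
        res = esd_outliers(x, k_max=5, alpha=0.05)
        assert 100 in res.flagged

    def test_location_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.standard_normal(80), [8.0, -7.0]])
        base = esd_outliers(x, k_max=5, alpha=0.05)
        scaled = esd_outliers(3.5 * x + 11.0, k_max=5, alpha=0.05)
        assert base.flagged == scaled.flagged
        assert base.R == pytest.approx(scaled.R, abs=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="n >= 3"):
            esd_outliers([1.0, 2.0])
        with pytest.raises(ValueError, match="k_max"):
            esd_outliers(np.arange(10.0), k_max=5)


@pytest.fixture(scope="module")
def farm_cohort(panels):
    lion, _, _ = panels
    rng = np.random.default_rng(6)
    cohort = []
    for i in range(60):
        fac = f"F{i % 2 + 1:02d}"
        cohort.append(_sample(f"T{i:03d}", sample_genotype(lion, rng), facility=fac))
    return cohort


class TestMatching:
    def test_identical_genotype_is_match(self, farm_cohort):
        src = farm_cohort[7]
        port = _sample(src.record.tag, StrGenotype(dict(src.genotype.alleles)),
                       facility=src.record.facility_id, site=Site.PORT)
        res = match_port_sample(port, farm_cohort)
        assert res.match_class is MatchClass.MATCH
        assert res.r_same_tag == 1.0
        assert res.esd_significant

    def test_reassigned_tag_same_facility(self, farm_cohort):
        declared = farm_cohort[3]
        other = next(
            s for s in farm_cohort[4:]
            if s.record.facility_id == declared.record.facility_id
        )
        port = _sample(declared.record.tag, StrGenotype(dict(other.genotype.alleles)),
                       facility=declared.record.facility_id, site=Site.PORT)
        res = match_port_sample(port, farm_cohort)
        assert res.match_class is MatchClass.REASSIGNED_SAME_FARM
        assert res.best_farm_tag == other.record.tag
        assert not res.cross_facility

    def test_unrelated_genotype_no_match(self, farm_cohort, panels):
        lion, _, _ = panels
        rng = np.random.default_rng(99)
        port = _sample(farm_cohort[0].record.tag, sample_genotype(lion, rng),
                       site=Site.PORT)
        res = match_port_sample(port, farm_cohort)
        assert res.match_class is MatchClass.NO_MATCH

    def test_absent_tag_is_its_own_error(self, farm_cohort):
        port = _sample("T999", StrGenotype(dict(farm_cohort[0].genotype.alleles)),
                       site=Site.PORT)
        with pytest.raises(TagAbsentError):
            match_port_sample(port, farm_cohort)

    def test_match_invariant_to_cohort_ordering(self, farm_cohort, panels):
        src = farm_cohort[11]
        port = _sample(src.record.tag, StrGenotype(dict(src.genotype.alleles)),
                       site=Site.PORT)
        a = match_port_sample(port, farm_cohort)
        reordered = list(reversed(farm_cohort))
        b = match_port_sample(port, reordered)
        assert a.match_class is b.match_class
        assert a.matched_farm_sample == b.matched_farm_sample


class TestDuplicates:
    def test_planted_identical_pair_found(self, panels):
        lion, _, _ = panels
        rng = np.random.default_rng(13)
        cohort = [_sample(f"T{i:03d}", sample_genotype(lion, rng)) for i in range(200)]
        clone = StrGenotype(dict(cohort[17].genotype.alleles))
        cohort.append(_sample("T900", clone))
        dups = find_duplicates(cohort)
        assert [(d.tag_a, d.tag_b) for d in dups] == [("T017", "T900")]
        assert dups[0].r == 1.0

    def test_tolerance_absorbs_dropout(self, panels):
        lion, _, _ = panels
        rng = np.random.default_rng(14)
        cohort = [_sample(f"T{i:03d}", sample_genotype(lion, rng)) for i in range(50)]
        corrupted = dict(cohort[5].genotype.alleles)
        locus = next(iter(corrupted))
        corrupted[locus] = (0, corrupted[locus][1])  # allelic dropout
        cohort.append(_sample("T900", StrGenotype(corrupted)))
        assert find_duplicates(cohort, mismatch_tolerance=0) == []
        dups = find_duplicates(cohort, mismatch_tolerance=1)
        assert [(d.tag_a, d.tag_b) for d in dups] == [("T005", "T900")]
        assert dups[0].n_mismatch == 1

    def test_clean_cohort_no_pairs(self, panels):
        lion, _, _ = panels
        rng = np.random.default_rng(15)
        cohort = [_sample(f"T{i:03d}", sample_genotype(lion, rng)) for i in range(300)]
        assert find_duplicates(cohort) == []


class TestClassification:
    def _mk_results(self, n_port, reassigned, no_match, year=2017):
        results = []
        for i in range(n_port):
            tag = f"T{i:03d}"
            cls = MatchClass.MATCH
            if i < reassigned:
                cls = MatchClass.REASSIGNED_SAME_FARM
            elif i < reassigned + no_match:
                cls = MatchClass.NO_MATCH
            results.append(
                MatchResult(f"PORT-{tag}", tag, cls, esd_significant=cls is not MatchClass.NO_MATCH)
            )
        return results

    def _records(self, n, site, year=2017):
        return [
            SampleRecord(f"{site.value}-T{i:03d}", f"T{i:03d}", "F01", site, year)
            for i in range(n)
        ]

    def test_port_proportion_like_2017_audit(self):
        results = self._mk_results(25, reassigned=3, no_match=0)
        ledger = classify_anomalies(
            results, [], [], self._records(800, Site.FARM), self._records(25, Site.PORT)
        )
        assert ledger.counts["PORT/2017"]["n_anomalies"] == 3
        assert ledger.counts["PORT/2017"]["proportion"] == pytest.approx(3 / 25)
        assert ledger.counts["FARM/2017"]["n_anomalies"] == 0
        assert all(
            e.interpretation == "TYPE_II_MISLABEL"
            for e in ledger.entries
            if e.anomaly == "REASSIGNED_TAG"
        )

    def test_duplicates_and_tiger_counted_at_farm(self):
        farm_records = self._records(800, Site.FARM, year=2018)
        port_records = self._records(102, Site.PORT, year=2018)
        results = self._mk_results(102, reassigned=1, no_match=4, year=2018)
        dups = [DuplicatePair("T500", "T501", 0, 1.0)]
        species = [
            SpeciesAssignment("FARM-T600", SpeciesCall.TIGER, 0.0, (0, 10), FinalCall.TIGER)
        ]
        ledger = classify_anomalies(results, dups, species, farm_records, port_records)
        assert ledger.counts["FARM/2018"]["n_anomalies"] == 3  # tiger + dup pair
        assert ledger.counts["PORT/2018"]["n_anomalies"] == 5
        by_anomaly = {}
        for e in ledger.entries:
            by_anomaly.setdefault(e.anomaly, []).append(e)
        assert len(by_anomaly["DUPLICATE_INDIVIDUAL"]) == 2
        assert all(e.interpretation == "TYPE_I_POOLING" for e in by_anomaly["POOLED_NO_MATCH"])

    def test_pending_results_rejected(self):
        pending = [MatchResult("PORT-T000", "T000", MatchClass.PENDING)]
        with pytest.raises(ValueError, match="resolved"):
            classify_anomalies(pending, [], [], self._records(10, Site.FARM), self._records(1, Site.PORT))

    def test_no_anomalies_all_zero(self):
        results = self._mk_results(25, reassigned=0, no_match=0)
        ledger = classify_anomalies(
            results, [], [], self._records(100, Site.FARM), self._records(25, Site.PORT)
        )
        assert all(c["n_anomalies"] == 0 for c in ledger.counts.values())
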