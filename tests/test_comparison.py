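"""Primary-vs-model comparison: two-sided Fisher vs enumeration, permutation
FDR control and power, fidelity classes, MAF correlation, contamination."""
import warnings

import numpy as np
import pytest

from tumorfidelity import comparison
from tumorfidelity.types import (
    AlleleCount,
    ComparisonRecord,
    FdrResult,
    InsufficientDataError,
    SiteObservation,
    ValidationError,
)

from oracles import fisher_two_sided_exact


def _record(primary, model, pos=1000):
    site = SiteObservation(chrom="chr1", pos=pos, ref="G", alt="T",
                           counts={"primary": AlleleCount(*primary),
                                   "model": AlleleCount(*model)},
                           mean_alt_quality=30.0)
    rec = ComparisonRecord(site=site, primary=site.counts["primary"],
                           model=site.counts["model"])
    rec.p_two_sided = comparison.compare_site(rec.primary, rec.model)
    return rec


def _null_records(rng, n, depth=60, maf=0.3):
    out = []
    for i in range(n):
        d1, d2 = rng.poisson(depth), rng.poisson(depth)
        a1, a2 = rng.binomial(d1, maf), rng.binomial(d2, maf)
        out.append(_record((d1 - a1, a1), (d2 - a2, a2), pos=i + 1))
    return out


class TestCompareSite:
    def test_identical_tables_give_one(self):
        p = comparison.compare_site(AlleleCount(30, 30), AlleleCount(30, 30))
        assert p == pytest.approx(1.0)

    def test_disjoint_tables_match_enumeration(self):
        p = comparison.compare_site(AlleleCount(50, 0), AlleleCount(0, 50))
        assert p == pytest.approx(fisher_two_sided_exact(50, 0, 0, 50), rel=1e-9)
        assert p < 1e-20

    def test_near_identical_frequencies(self):
        # PTEN-like counts in both samples: no frequency change
        p = comparison.compare_site(AlleleCount(43, 45), AlleleCount(40, 44))
        assert p == pytest.approx(fisher_two_sided_exact(43, 45, 40, 44), rel=1e-9)
        assert p > 0.5

    def test_exhaustive_agreement_small_margins(self):
        for n1 in range(1, 11):
            for n2 in range(1, 11):
                for alt_total in range(n1 + n2 + 1):
                    for b in range(max(0, alt_total - n2),
                                   min(n1, alt_total) + 1):
                        d = alt_total - b
                        impl = comparison.compare_site(
                            AlleleCount(n1 - b, b), AlleleCount(n2 - d, d))
                        exact = fisher_two_sided_exact(n1 - b, b, n2 - d, d)
                        assert impl == pytest.approx(exact, abs=1e-10)

    def test_zero_depth_everywhere_rejected(self):
        with pytest.raises(ValidationError):
            comparison.compare_site(AlleleCount(0, 0), AlleleCount(0, 0))


class TestPermutationFdr:
    def test_null_significant_fraction_controlled(self, rng):
        records = _null_records(rng, 600)
        fdr = comparison.permutation_fdr(records, n_permutations=300, seed=1)
        n_sig = sum(1 for r in records if r.p_two_sided <= fdr.p_threshold)
        mc_se = np.sqrt(0.05 * 0.95 / len(records))
        assert n_sig / len(records) <= 0.05 + 2 * mc_se

    def test_power_with_controlled_fdr(self, rng):
        # 80% null sites + 20% with a true MAF shift of 0.3 at 60x
        null = _null_records(rng, 400, maf=0.3)
        shifted = []
        for i in range(100):
            d1, d2 = rng.poisson(60), rng.poisson(60)
            a1, a2 = rng.binomial(d1, 0.2), rng.binomial(d2, 0.5)
            shifted.append(_record((d1 - a1, a1), (d2 - a2, a2), pos=10_000 + i))
        records = null + shifted
        fdr = comparison.permutation_fdr(records, n_permutations=300, seed=2)
        sig_null = sum(1 for r in null if r.p_two_sided <= fdr.p_threshold)
        sig_shift = sum(1 for r in shifted if r.p_two_sided <= fdr.p_threshold)
        assert sig_shift > 0
        total_sig = sig_null + sig_shift
        mc_se = np.sqrt(0.05 * 0.95 / max(total_sig, 1))
        assert sig_null / max(total_sig, 1) <= 0.05 + 2 * mc_se + 0.05

    def test_deterministic_under_seed(self, rng):
        records = _null_records(rng, 50)
        a = comparison.permutation_fdr(records, n_permutations=150, seed=9)
        b = comparison.permutation_fdr(records, n_permutations=150, seed=9)
        assert a == b

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValidationError):
            comparison.permutation_fdr(_null_records(rng, 5), n_permutations=10)

    def test_empty_records_rejected(self):
        with pytest.raises(ValidationError):
            comparison.permutation_fdr([], n_permutations=100)


class TestClassifyRecords:
    def test_shared_constant(self):
        rec = _record((30, 30), (29, 31))
        out = comparison.classify_records([rec], FdrResult(0.01, 100, 0.0, 0))
        assert out[0].q_class == "shared_constant"

    def test_primary_only_when_model_lacks_detection(self):
        rec = _record((30, 30), (60, 0))
        out = comparison.classify_records([rec], FdrResult(0.01, 100, 0.0, 0))
        assert rec.p_two_sided <= 0.01
        assert out[0].q_class == "primary_only"

    def test_shared_changing_when_detected_in_both(self):
        rec = _record((40, 20), (20, 40))
        assert rec.p_two_sided <= 0.01
        out = comparison.classify_records([rec], FdrResult(0.01, 100, 0.0, 0))
        assert out[0].q_class == "shared_changing"

    def test_detected_in_one_without_significance_stays_shared(self):
        rec = _record((58, 2), (57, 1))  # model below 2-read detection floor
        out = comparison.classify_records([rec], FdrResult(0.0, 100, 0.0, 0))
        assert out[0].q_class == "shared_constant"

    def test_partition_is_exhaustive_and_exclusive(self, rng):
        records = _null_records(rng, 200)
        fdr = comparison.permutation_fdr(records, n_permutations=150, seed=3)
        comparison.classify_records(records, fdr)
        counts = comparison.class_counts(records)
        assert sum(counts.values()) == len(records)


class TestMafCorrelation:
    def test_proportional_mafs_give_unit_correlation(self):
        records = [_record((60 - a, a), (60 - a, a)) for a in (10, 20, 30, 40)]
        r, n = comparison.maf_correlation(records)
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_faithful_model_exceeds_published_bound(self, rng):
        # same clonal structure, purities 0.8 vs 1.0, 60x, 300 sites -> r > 0.7
        records = []
        for i in range(300):
            f = rng.choice([0.5, 0.25])
            d1, d2 = rng.poisson(60), rng.poisson(60)
            a1 = rng.binomial(d1, f * 0.8)
            a2 = rng.binomial(d2, f)
            records.append(_record((d1 - a1, a1), (d2 - a2, a2), pos=i + 1))
        r, n = comparison.maf_correlation(records, min_depth=30)
        assert r > 0.7

    def test_depth_floor_filters_sites(self):
        records = [_record((60, 30), (60, 30)),
                   _record((5, 3), (60, 30)),
                   _record((60, 30), (60, 30)),
                   _record((60, 30), (60, 30))]
        _, n = comparison.maf_correlation(records, min_depth=30)
        assert n == 3

    def test_too_few_qualifying_sites_rejected(self):
        with pytest.raises(InsufficientDataError):
            comparison.maf_correlation([_record((5, 3), (5, 3))] * 5, min_depth=30)

    def test_spearman_option(self):
        records = [_record((60 - a, a), (60 - a, a)) for a in (5, 15, 25, 35)]
        r, _ = comparison.maf_correlation(records, method="spearman")
        assert r == pytest.approx(1.0)


class TestEstimateContamination:
    def _classified(self, records):
        for r in records:
            r.q_class = "shared_constant"
        return records

    def test_equal_mafs_give_zero(self):
        records = self._classified([_record((30, 30), (30, 30))] * 12)
        with pytest.warns(UserWarning, match="neutral"):
            assert comparison.estimate_contamination(records) == 0.0

    def test_halved_maf_gives_half(self):
        records = self._classified([_record((45, 15), (30, 30))] * 12)
        with pytest.warns(UserWarning):
            assert comparison.estimate_contamination(records) == pytest.approx(0.5)

    @pytest.mark.parametrize("c_true", [0.09, 0.11, 0.25, 0.41])
    def test_parameter_recovery(self, c_true, rng):
        # pure model, contaminated primary, 150 clonal het sites at 60x
        records = []
        for i in range(150):
            d1, d2 = rng.poisson(60), rng.poisson(60)
            a1 = rng.binomial(d1, 0.5 * (1 - c_true))
            a2 = rng.binomial(d2, 0.5)
            records.append(_record((d1 - a1, a1), (d2 - a2, a2), pos=i + 1))
        self._classified(records)
        with pytest.warns(UserWarning):
            c_hat = comparison.estimate_contamination(records)
        assert abs(c_hat - c_true) <= 0.05

    def test_mean_bias_small_at_quarter_contamination(self):
        # 50 replicates at c = 0.25: |mean bias| <= 0.02
        ests = []
        for rep in range(50):
            r_ = np.random.default_rng(1000 + rep)
            records = []
            for i in range(150):
                d1, d2 = r_.poisson(60), r_.poisson(60)
                a1 = r_.binomial(d1, 0.5 * 0.75)
                a2 = r_.binomial(d2, 0.5)
                records.append(_record((d1 - a1, a1), (d2 - a2, a2), pos=i + 1))
            self._classified(records)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ests.append(comparison.estimate_contamination(records))
        assert abs(np.mean(ests) - 0.25) <= 0.02

    def test_unidirectional_change_when_primary_contaminated(self, rng):
        # contamination only dilutes the primary, so nearly all significant
        # frequency changes point toward the model
        records = []
        for i in range(400):
            d1, d2 = rng.poisson(60), rng.poisson(60)
            a1 = rng.binomial(d1, 0.5 * 0.6)
            a2 = rng.binomial(d2, 0.5)
            records.append(_record((d1 - a1, a1), (d2 - a2, a2), pos=i + 1))
        fdr = comparison.permutation_fdr(records, n_permutations=200, seed=4)
        comparison.classify_records(records, fdr)
        changing = [r for r in records if r.q_class == "shared_changing"]
        assert len(changing) >= 10
        toward_model = sum(1 for r in changing if r.model_maf > r.primary_maf)
        assert toward_model / len(changing) >= 0.9

    def test_too_few_sites_rejected(self):
        records = self._classified([_record((30, 30), (30, 30))] * 5)
        with pytest.raises(InsufficientDataError), \
                warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comparison.estimate_contamination(records)
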