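"""CNA pipeline: GC correction, logR, segmentation, state calls, arm rule,
LOH, concordance, clustering."""
import re

import numpy as np
import pytest

from tumorfidelity import cna
from tumorfidelity.types import (
    AlleleCount,
    CopySegment,
    SiteObservation,
    TargetProbe,
    ValidationError,
)


def _probe(chrom="chr1", start=0, gc=0.45, normal=240.0, tumor=240.0, logr=None):
    p = TargetProbe(chrom=chrom, start=start, end=start + 200, gc=gc,
                    normal_cov=normal, tumor_cov=tumor)
    if logr is not None:
        p.logr = logr
    return p


def _probes_with_logr(values, chrom="chr1", spacing=1000):
    out = []
    for i, v in enumerate(values):
        p = _probe(chrom=chrom, start=i * spacing)
        p.logr = float(v)
        out.append(p)
    return out


class TestGcCorrect:
    def test_pure_gc_function_flattens(self, rng):
        # coverage an exact function of GC: corrected coverage is constant
        gcs = rng.uniform(0.3, 0.7, 600)
        probes = [_probe(start=i * 300, gc=float(g),
                         normal=200 * (1 - (g - 0.45) ** 2 * 3),
                         tumor=200 * (1 - (g - 0.45) ** 2 * 3))
                  for i, g in enumerate(gcs)]
        corrected = cna.gc_correct(probes)
        cov = np.array([p.normal_cov for p in corrected])
        assert cov.std() / cov.mean() < 0.05

    def test_unbiased_input_nearly_unchanged(self, rng):
        probes = [_probe(start=i * 300, gc=float(g), normal=v, tumor=v)
                  for i, (g, v) in enumerate(zip(rng.uniform(0.3, 0.7, 500),
                                                 rng.normal(240, 5, 500)))]
        corrected = cna.gc_correct(probes)
        before = np.array([p.normal_cov for p in probes])
        after = np.array([p.normal_cov for p in corrected])
        assert np.abs(after / before - 1).mean() < 0.01

    def test_same_gc_everywhere_is_identity(self):
        probes = [_probe(start=i * 300, gc=0.5, normal=100 + i, tumor=90 + i)
                  for i in range(30)]
        corrected = cna.gc_correct(probes)
        for a, b in zip(probes, corrected):
            assert b.normal_cov == pytest.approx(a.normal_cov)
            assert b.tumor_cov == pytest.approx(a.tumor_cov)

    def test_reduces_logr_gc_correlation(self, rng):
        # tumor-only GC trend: strong corr(logR, GC) before, < 0.05 after
        gcs = rng.uniform(0.3, 0.7, 800)
        probes = []
        for i, g in enumerate(gcs):
            base = float(rng.normal(240, 10))
            trend = float(np.exp(1.5 * (g - 0.5)))
            probes.append(_probe(start=i * 300, gc=float(g), normal=base,
                                 tumor=base * trend * float(rng.normal(1, 0.05))))
        before = cna.compute_logr(probes)
        r0 = np.corrcoef(gcs, [p.logr for p in before])[0, 1]
        after = cna.compute_logr(cna.gc_correct(probes))
        r1 = np.corrcoef(gcs, [p.logr for p in after])[0, 1]
        assert abs(r0) > 0.3
        assert abs(r1) < 0.05


class TestComputeLogr:
    def test_equal_normalized_coverage_gives_zero(self):
        probes = [_probe(start=i * 300, normal=100, tumor=100) for i in range(5)]
        for p in cna.compute_logr(probes):
            assert p.logr == pytest.approx(0.0)

    def test_trisomic_probe_after_normalization(self):
        # genome-wide neutral with one 3-copy probe: its logR ~ log2(1.5)
        probes = [_probe(start=i * 300, normal=200, tumor=200) for i in range(999)]
        probes.append(_probe(start=999 * 300, normal=200, tumor=300))
        out = cna.compute_logr(probes)
        assert out[-1].logr == pytest.approx(np.log2(1.5), abs=0.01)

    def test_zero_normal_coverage_marks_nc(self):
        probes = [_probe(start=0, normal=0, tumor=100),
                  _probe(start=300, normal=200, tumor=200)]
        out = cna.compute_logr(probes)
        assert out[0].nc is True and np.isnan(out[0].logr)
        assert out[1].nc is False


class TestSegment:
    def test_constant_chromosome_single_segment(self, rng):
        probes = _probes_with_logr(rng.normal(0, 0.1, 80))
        segs = cna.segment(probes, seed=0, n_permutations=300)
        assert len(segs) == 1
        assert segs[0].n_probes == 80

    def test_breakpoint_recovery(self):
        # step 0 -> 0.58 at probe 50 of 100, sigma 0.1: breakpoint within
        # +/-3 probes in >=95% of seeds
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            r_ = np.random.default_rng(seed)
            vals = np.concatenate([r_.normal(0, 0.1, 50), r_.normal(0.58, 0.1, 50)])
            probes = _probes_with_logr(vals)
            segs = cna.segment(probes, seed=seed, n_permutations=500)
            boundaries = {s.start // 1000 for s in segs[1:]}
            hits += any(abs(b - 50) <= 3 for b in boundaries)
        assert hits / n_seeds >= 0.95

    def test_tiny_chromosome_untested(self, rng):
        probes = _probes_with_logr([0.0, 1.0, 0.0, 1.0])
        segs = cna.segment(probes, seed=0)
        assert len(segs) == 1

    def test_probe_counts_partition_chromosome(self, rng):
        vals = np.concatenate([rng.normal(0, 0.1, 40), rng.normal(0.8, 0.1, 40)])
        probes = _probes_with_logr(vals)
        segs = cna.segment(probes, seed=1, n_permutations=300)
        assert sum(s.n_probes for s in segs) == len(probes)
        # bp spans tile the probe span without overlap
        for a, b in zip(segs, segs[1:]):
            assert a.end <= b.start


class TestCallSegments:
    def test_all_neutral_no_hc(self, rng):
        probes = _probes_with_logr(rng.normal(0, 0.1, 60))
        segs = cna.segment(probes, seed=0, n_permutations=200)
        segs = cna.call_segments(segs, probes)
        assert all(s.call == "neutral" and s.confidence != "hc" for s in segs)

    def test_extreme_amplification_graded_hc(self, rng):
        # one segment at logR 2.2 among neutral noise: high-confidence amp
        neutral = rng.normal(0, 0.1, 60)
        amp = rng.normal(2.2, 0.1, 10)
        probes = (_probes_with_logr(neutral, chrom="chr1")
                  + _probes_with_logr(amp, chrom="chr2"))
        segs = cna.segment(probes, seed=0, n_permutations=200)
        segs = cna.call_segments(segs, probes)
        calls = {s.chrom: (s.call, s.confidence) for s in segs}
        assert calls["chr2"] == ("amp", "hc")

    def test_no_neutral_segments_skips_grading(self, rng):
        probes = _probes_with_logr(rng.normal(2.0, 0.05, 40))
        segs = cna.segment(probes, seed=0, n_permutations=200)
        with pytest.warns(UserWarning, match="neutral"):
            segs = cna.call_segments(segs, probes)
        assert all(s.confidence == "standard" for s in segs)


class TestCallArms:
    CYTO = [("chr1", 0, 5000, "p11", "gneg"), ("chr1", 5000, 10000, "q11", "gneg")]

    def _seg(self, start, end, call):
        s = CopySegment("chr1", start, end, 0.0, 5)
        s.call = call
        return s

    def test_quarter_deleted_arm_fires(self):
        segs = [self._seg(0, 1250, "del"), self._seg(1250, 5000, "neutral")]
        arms = cna.call_arms(segs, self.CYTO)
        p = next(a for a in arms if a.arm == "p")
        assert p.call == "del"
        assert p.fraction_bp_del == pytest.approx(0.25)

    def test_nineteen_percent_stays_neutral(self):
        segs = [self._seg(0, 950, "del"), self._seg(950, 5000, "neutral")]
        p = next(a for a in cna.call_arms(segs, self.CYTO) if a.arm == "p")
        assert p.call == "neutral"

    def test_whole_arm_amplification(self):
        segs = [self._seg(0, 5000, "amp"), self._seg(5000, 10000, "neutral")]
        arms = {a.arm: a.call for a in cna.call_arms(segs, self.CYTO)}
        assert arms == {"p": "amp", "q": "neutral"}

    def test_mixed_directions_count_separately(self):
        # 15% amp + 15% del on one arm: neither direction passes 20%
        segs = [self._seg(0, 750, "amp"), self._seg(750, 1500, "del"),
                self._seg(1500, 5000, "neutral")]
        p = next(a for a in cna.call_arms(segs, self.CYTO) if a.arm == "p")
        assert p.call == "neutral"


class TestCallLoh:
    def _het(self, pos, baf, depth=60):
        alt = int(round(baf * depth))
        return SiteObservation(chrom="chr1", pos=pos, ref="A", alt="G",
                               counts={"primary": AlleleCount(depth - alt, alt)},
                               mean_alt_quality=30.0)

    def test_balanced_baf_not_loh(self):
        seg = CopySegment("chr1", 0, 10_000, 0.0, 20)
        sites = [self._het(100 * (i + 1), 0.5) for i in range(15)]
        assert cna.call_loh(sites, [seg])[0].loh is False

    def test_collapsed_baf_flags_loh(self):
        seg = CopySegment("chr1", 0, 10_000, -0.8, 20)
        sites = [self._het(100 * (i + 1), 0.05) for i in range(15)]
        assert cna.call_loh(sites, [seg])[0].loh is True

    def test_too_few_het_sites_guard(self):
        seg = CopySegment("chr1", 0, 10_000, -0.8, 20)
        sites = [self._het(100 * (i + 1), 0.05) for i in range(5)]
        assert cna.call_loh(sites, [seg])[0].loh is False


class TestConcordance:
    def _segments(self, calls, hc=True):
        out = []
        for i, call in enumerate(calls):
            s = CopySegment("chr1", i * 1000, (i + 1) * 1000, 0.0, 5)
            s.call = call
            s.confidence = "hc" if hc and call in ("amp", "del") else "standard"
            out.append(s)
        return out

    TARGETS = [("chr1", i * 1000, i * 1000 + 200) for i in range(4)]

    def test_identical_sets_fully_concordant(self):
        a = self._segments(["amp", "del", "neutral", "amp"])
        table, frac = cna.cna_concordance(a, a, self.TARGETS)
        assert frac == 1.0

    def test_opposite_calls_fully_discordant(self):
        a = self._segments(["amp", "amp", "amp", "amp"])
        b = self._segments(["del", "del", "del", "del"])
        _, frac = cna.cna_concordance(a, b, self.TARGETS)
        assert frac == 0.0

    def test_contingency_totals_match_targeted_hc_bp(self):
        a = self._segments(["amp", "del", "neutral", "neutral"])
        b = self._segments(["amp", "neutral", "neutral", "del"])
        table, _ = cna.cna_concordance(a, b, self.TARGETS)
        # hc regions: probes 0,1 (from a) and 0,3 (from b) -> 3 x 200 bp
        assert sum(table.values()) == 600

    def test_faithful_pair_high_concordance(self):
        from tumorfidelity import CohortConfig, simulate_cohort
        cfg = CohortConfig(seed=21, n_somatic_sites=20, n_germline_sites=20,
                           n_reads=0, mouse_read_fractions=(0.0,) * 4,
                           primary_purities=(0.9,) * 4)
        cohort = simulate_cohort(cfg)
        pdat = cohort.patients[0]
        seg_by_sample = {}
        for sample in ("primary", "model"):
            probes = cna.compute_logr(cna.gc_correct(pdat.probes[sample]))
            segs = cna.call_segments(
                cna.segment(probes, seed=5, n_permutations=300), probes)
            seg_by_sample[sample] = segs
        targets = [(p.chrom, p.start, p.end) for p in pdat.probes["primary"]]
        _, frac = cna.cna_concordance(seg_by_sample["primary"],
                                      seg_by_sample["model"], targets)
        assert frac >= 0.9


class TestClusterSamples:
    def test_duplicate_sample_joins_at_zero_height(self):
        mat = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 5.0]])
        nwk = cna.cluster_samples(mat, ["a", "b", "c"])
        assert re.search(r"\(a:0(\.0+)?,b:0(\.0+)?\)", nwk)

    def test_single_sample_tree(self):
        assert cna.cluster_samples(np.array([[1.0]]), ["only"]) == "only;"

    def test_cohort_pairs_primary_with_own_model(self, small_cohort):
        samples = {}
        for pdat in small_cohort.patients:
            for sample in ("primary", "model"):
                probes = cna.compute_logr(cna.gc_correct(pdat.probes[sample]))
                segs = cna.call_segments(
                    cna.segment(probes, seed=3, n_permutations=200), probes)
                samples[f"P{pdat.patient}_{sample}"] = (segs, probes)
        mat, names, _ = cna.hc_segment_logr_matrix(samples)
        nwk = cna.cluster_samples(mat, names)
        for pid in range(4):
            assert re.search(
                rf"\(P{pid}_model:[^,()]+,P{pid}_primary:[^,()]+\)", nwk), nwk

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            cna.cluster_samples(np.zeros((2, 3)), ["a"])
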