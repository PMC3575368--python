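"""Statistical primary-vs-model comparison of somatic mutant allele
frequencies.

Each somatic site's primary and model allele counts form a 2x2 table tested
with a two-sided Fisher exact test. The significance threshold is chosen to
control a permutation-estimated false discovery rate: under the null the
pooled reads at a site are exchangeable between the two samples, so null
p-values are generated by hypergeometric re-splits that preserve both sample
depths and the total alt count. Sites are then classified as shared-constant,
shared-changing, or unique to one sample, and the primary's normal-DNA
contamination is estimated from the shrinkage of its mutant allele
frequencies relative to a pure model.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import hypergeom, pearsonr, spearmanr

from .types import (
    AlleleCount,
    ComparisonRecord,
    FdrResult,
    InsufficientDataError,
    ValidationError,
)

_REL_GATE = 1.0 + 1e-7  # two-sided gate matching the conventional definition


def _two_sided_table(primary: AlleleCount, model: AlleleCount):
    """Support and two-sided p-value lookup for all tables sharing this
    site's margins. Returns (support ks, p-value per k)."""
    n1 = primary.depth
    n2 = model.depth
    total = n1 + n2
    alt_total = primary.alt_count + model.alt_count
    # k = primary alt count
    lo = max(0, alt_total - n2)
    hi = min(n1, alt_total)
    ks = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(ks, total, alt_total, n1)
    pvals = np.array([pmf[pmf <= pmf[i] * _REL_GATE].sum() for i in range(ks.size)])
    return ks, np.minimum(pvals, 1.0)


def compare_site(primary: AlleleCount, model: AlleleCount) -> float:
    """Two-sided Fisher exact p on (primary ref/alt vs model ref/alt)."""
    if primary.depth + model.depth == 0:
        raise ValidationError("both samples have zero depth")
    ks, pvals = _two_sided_table(primary, model)
    return float(pvals[int(primary.alt_count - ks[0])])


def build_records(sites, primary_sample: str = "primary",
                  model_sample: str = "model") -> list[ComparisonRecord]:
    """Assemble comparison records (with two-sided p) from site observations."""
    records = []
    for s in sites:
        rec = ComparisonRecord(site=s, primary=s.counts[primary_sample],
                               model=s.counts[model_sample])
        rec.p_two_sided = compare_site(rec.primary, rec.model)
        records.append(rec)
    return records


def permutation_fdr(records: list[ComparisonRecord], n_permutations: int = 1000,
                    seed: int = 0, target_fdr: float = 0.05) -> FdrResult:
    """Pick the largest p-value threshold with permutation-estimated FDR at
    or below ``target_fdr``.

    For each permutation, the pooled reads at every site are re-split
    between primary and model preserving both depths (hypergeometric
    resampling) and the two-sided p recomputed. FDR(t) is the mean null
    count of p <= t divided by the observed count of p <= t, evaluated on
    the observed p-value grid. Deterministic under a fixed seed.
    """
    if not records:
        raise ValidationError("permutation_fdr needs at least one record")
    if n_permutations < 100:
        raise ValidationError("n_permutations must be >= 100")
    rng = np.random.default_rng(seed)

    obs = np.empty(len(records))
    null_chunks = []
    for i, rec in enumerate(records):
        ks, pvals = _two_sided_table(rec.primary, rec.model)
        obs[i] = pvals[int(rec.primary.alt_count - ks[0])]
        total = rec.primary.depth + rec.model.depth
        alt_total = rec.primary.alt_count + rec.model.alt_count
        if total == 0:
            null_chunks.append(np.ones(n_permutations))
            continue
        draws = rng.hypergeometric(alt_total, total - alt_total,
                                   rec.primary.depth, size=n_permutations)
        null_chunks.append(pvals[draws - ks[0]])
    null = np.vstack(null_chunks)  # sites x permutations

    grid = np.unique(obs)
    n_obs = np.searchsorted(np.sort(obs), grid, side="right")
    null_sorted = np.sort(null.ravel())
    mean_null = np.searchsorted(null_sorted, grid, side="right") / n_permutations
    fdr = mean_null / np.maximum(n_obs, 1)
    ok = np.nonzero(fdr <= target_fdr)[0]
    if ok.size == 0:
        warnings.warn("no p-value threshold achieves the target FDR; "
                      "nothing is significant")
        return FdrResult(0.0, n_permutations, 0.0, seed)
    i = int(ok.max())
    return FdrResult(float(grid[i]), n_permutations, float(fdr[i]), seed)


def classify_records(records: list[ComparisonRecord], fdr: FdrResult,
                     min_alt_reads: int = 2, min_alt_fraction: float = 0.05
                     ) -> list[ComparisonRecord]:
    """Assign each record a fidelity class (in place; records returned).

    A mutation is "detected" in a sample at >= ``min_alt_reads`` alt reads
    and >= ``min_alt_fraction`` MAF. Detected in both: shared_constant if
    p > threshold else shared_changing. Detected in exactly one: unique to
    that sample if p <= threshold, else shared_constant (no evidence of
    absence). Classes are exhaustive and exclusive.
    """
    t = fdr.p_threshold
    for rec in records:
        in_primary = (rec.primary.alt_count >= min_alt_reads
                      and rec.primary_maf >= min_alt_fraction)
        in_model = (rec.model.alt_count >= min_alt_reads
                    and rec.model_maf >= min_alt_fraction)
        significant = rec.p_two_sided <= t
        if in_primary and in_model:
            rec.q_class = "shared_changing" if significant else "shared_constant"
        elif in_primary and not in_model:
            rec.q_class = "primary_only" if significant else "shared_constant"
        elif in_model and not in_primary:
            rec.q_class = "model_only" if significant else "shared_constant"
        else:
            # below detection in both; no evidence of difference
            rec.q_class = "shared_constant"
    return records


def maf_correlation(records: list[ComparisonRecord], min_depth: int = 30,
                    method: str = "pearson") -> tuple[float, int]:
    """Correlation of primary vs model MAF over sites covered by at least
    ``min_depth`` reads in both samples. Returns (r, n_used)."""
    pairs = [(r.primary_maf, r.model_maf) for r in records
             if r.primary.depth >= min_depth and r.model.depth >= min_depth]
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"need >= 3 sites at depth >= {min_depth} in both samples, got {len(pairs)}")
    x, y = zip(*pairs)
    if method == "pearson":
        r = pearsonr(x, y)[0]
    elif method == "spearman":
        r = spearmanr(x, y)[0]
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return float(r), len(pairs)


def estimate_contamination(records: list[ComparisonRecord],
                           neutral_segments=None, min_sites: int = 10) -> float:
    """Estimate the primary's normal-DNA contamination, assuming a pure model.

    At a copy-neutral heterozygous somatic site, the primary's MAF is the
    model's scaled by (1 - c), so c = 1 - median(primary_maf / model_maf)
    over shared sites, clamped to [0, 1]. When copy-neutral segments are
    provided, only sites inside them qualify; otherwise all shared sites are
    used with a warning.
    """
    qualifying = [r for r in records
                  if r.q_class in ("shared_constant", "shared_changing")
                  and r.model_maf > 0]
    if neutral_segments is not None:
        neutral = [(s.chrom, s.start, s.end) for s in neutral_segments
                   if s.call == "neutral"]
        def in_neutral(rec):
            return any(c == rec.site.chrom and s < rec.site.pos <= e
                       for c, s, e in neutral)
        qualifying = [r for r in qualifying if in_neutral(r)]
    else:
        warnings.warn("no copy-neutral segments supplied; using all shared sites")
    if len(qualifying) < min_sites:
        raise InsufficientDataError(
            f"contamination estimate needs >= {min_sites} qualifying sites, "
            f"got {len(qualifying)}")
    ratios = np.array([r.primary_maf / r.model_maf for r in qualifying])
    c = 1.0 - float(np.median(ratios))
    return float(min(max(c, 0.0), 1.0))


def class_counts(records: list[ComparisonRecord]) -> dict[str, int]:
    counts = {"shared_constant": 0, "shared_changing": 0,
              "primary_only": 0, "model_only": 0}
    for r in records:
        if r.q_class is None:
            raise ValidationError("records must be classified first")
        counts[r.q_class] += 1
    return counts
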