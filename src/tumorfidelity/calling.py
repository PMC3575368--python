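"""Tumor–normal variant calling from pileup allele counts.

A site is called somatic when the tumor shows significant alternate-allele
enrichment over the matched germline (right-tailed Fisher exact p <= 0.05),
the germline alt fraction does not exceed 5% (removes germline variants
mis-called somatic), and minimum coverage/support floors are met. Indels use
stricter floors: >= 10x tumor coverage and >= 3 supporting reads. Germline
calls require a heterozygous-level alt fraction in the normal; loss of
heterozygosity is a germline-het site whose tumor allele balance departs
significantly toward 0 or 1.
"""
from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import fisher_exact, hypergeom

from .types import SiteObservation, ValidationError, VariantCall


@dataclass(frozen=True)
class CallThresholds:
    """Caller settings. The Fisher alpha, the 5% normal alt-fraction cap and
    the indel floors (10x coverage, 3 alt reads, <5% germline) form the
    core calling contract; the SNV coverage/support floors and the het
    threshold are conventional defaults and configurable."""

    fisher_alpha: float = 0.05
    max_normal_alt_fraction: float = 0.05
    min_coverage: int = 8
    min_alt_reads: int = 2
    het_normal_fraction: float = 0.20
    indel_min_coverage: int = 10
    indel_min_alt_reads: int = 3
    loh_alpha: float = 0.05


def _check_table(a: int, b: int, c: int, d: int) -> None:
    if min(a, b, c, d) < 0:
        raise ValidationError("contingency counts must be non-negative")
    if a + b + c + d == 0:
        raise ValidationError("all-zero contingency table")


def fisher_right_tail(a: int, b: int, c: int, d: int) -> float:
    """Right-tailed Fisher exact p for tumor alt-allele enrichment.

    The 2x2 table is (normal ref/alt = a/b; tumor ref/alt = c/d). With
    margins fixed, the tumor alt count follows a hypergeometric law; the
    returned p is P(tumor alt >= d | margins), in (0, 1].
    """
    _check_table(a, b, c, d)
    total = a + b + c + d
    alt_total = b + d
    tumor_depth = c + d
    # sf(d-1) = P(X >= d) for X ~ Hypergeom(total, alt_total, tumor_depth)
    return float(hypergeom.sf(d - 1, total, alt_total, tumor_depth))


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p on the 2x2 table [[a, b], [c, d]]."""
    _check_table(a, b, c, d)
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def call_site(site: SiteObservation, tumor_sample: str = "primary",
              normal_sample: str = "germline",
              thresholds: CallThresholds = CallThresholds()) -> VariantCall:
    """Call one site as somatic, germline, loh, or reference.

    Indel sites are routed through :func:`call_indel`.
    """
    if site.variant_type == "indel":
        return call_indel(site, tumor_sample, normal_sample, thresholds)
    normal = site.counts[normal_sample]
    tumor = site.counts[tumor_sample]
    p = fisher_right_tail(normal.ref_count, normal.alt_count,
                          tumor.ref_count, tumor.alt_count)
    filters = {
        "fisher": p <= thresholds.fisher_alpha,
        "normal_fraction": normal.alt_fraction <= thresholds.max_normal_alt_fraction,
        "coverage": (normal.depth >= thresholds.min_coverage
                     and tumor.depth >= thresholds.min_coverage),
        "alt_support": tumor.alt_count >= thresholds.min_alt_reads,
    }
    if all(filters.values()):
        return VariantCall(site, "somatic", somatic_p=p, filters=filters)
    if normal.alt_fraction >= thresholds.het_normal_fraction:
        # germline; check for loss of heterozygosity at het sites
        if normal.alt_fraction <= 1.0 - thresholds.het_normal_fraction and tumor.depth > 0:
            p2 = fisher_two_sided(normal.ref_count, normal.alt_count,
                                  tumor.ref_count, tumor.alt_count)
            departs = abs(tumor.alt_fraction - 0.5) > abs(normal.alt_fraction - 0.5)
            if p2 <= thresholds.loh_alpha and departs:
                return VariantCall(site, "loh", somatic_p=p, filters=filters)
        return VariantCall(site, "germline", somatic_p=p, filters=filters)
    return VariantCall(site, "reference", somatic_p=p, filters=filters)


def call_indel(site: SiteObservation, tumor_sample: str = "primary",
               normal_sample: str = "germline",
               thresholds: CallThresholds = CallThresholds()) -> VariantCall:
    """Call an indel site under the stricter indel rules: >= 10x tumor
    coverage, >= 3 alt reads, germline alt fraction < 5%, Fisher p <= alpha."""
    normal = site.counts[normal_sample]
    tumor = site.counts[tumor_sample]
    p = fisher_right_tail(normal.ref_count, normal.alt_count,
                          tumor.ref_count, tumor.alt_count)
    filters = {
        "fisher": p <= thresholds.fisher_alpha,
        "normal_fraction": normal.alt_fraction < thresholds.max_normal_alt_fraction,
        "coverage": tumor.depth >= thresholds.indel_min_coverage,
        "alt_support": tumor.alt_count >= thresholds.indel_min_alt_reads,
    }
    if all(filters.values()):
        return VariantCall(site, "somatic", somatic_p=p, filters=filters)
    if normal.alt_fraction >= thresholds.het_normal_fraction:
        return VariantCall(site, "germline", somatic_p=p, filters=filters)
    return VariantCall(site, "reference", somatic_p=p, filters=filters)


def call_sites(sites: list[SiteObservation], tumor_sample: str = "primary",
               normal_sample: str = "germline",
               thresholds: CallThresholds = CallThresholds()) -> list[VariantCall]:
    """Call every site; order preserved."""
    return [call_site(s, tumor_sample, normal_sample, thresholds) for s in sites]


def restrict_to_targets(sites: list[SiteObservation],
                        targets: list[tuple[str, int, int]]) -> list[SiteObservation]:
    """Keep sites whose 1-based position falls inside a 0-based half-open
    target interval (kept when start < pos <= end). Output order preserved."""
    import numpy as np

    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in targets:
        if end <= start:
            raise ValidationError(f"invalid target interval {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((start, end))
    arrays = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        arrays[chrom] = (np.array([s for s, _ in ivs]), np.array([e for _, e in ivs]))
    kept = []
    for site in sites:
        if site.chrom not in arrays:
            continue
        starts, ends = arrays[site.chrom]
        i = int(np.searchsorted(starts, site.pos, side="left")) - 1
        if i >= 0 and site.pos <= ends[i]:
            kept.append(site)
    return kept
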