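"""Cohort-level summaries and end-to-end pipeline orchestration.

Summaries mirror how exome studies report a somatic mutation landscape:
per-consequence-class counts and percentages, the non-synonymous to
synonymous ratio, transition/transversion ratio, known-variant fraction,
and overlap with a user-supplied gene list. ``run_pipeline`` drives the full
synthetic workflow: simulate, remove host reads, quality-filter, call
somatic variants, compare primary to model, call CNAs, and cluster samples.
"""
from __future__ import annotations

import json
import math
import os
import warnings

import numpy as np

from . import calling, cna, comparison, io, quality, synthetic, xenofilter
from .types import (
    NONSYNONYMOUS_CLASSES,
    InsufficientDataError,
    VariantCall,
)

_CODING_CLASSES = NONSYNONYMOUS_CLASSES + ("synonymous",)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def class_distribution_from_counts(counts: dict[str, int]) -> dict:
    """Class summary from per-consequence mutation counts.

    Returns counts, integer percentages (rounded half-up, over coding and
    splice-site mutations), and the non-synonymous/synonymous ratio
    (non-synonymous includes missense, nonsense, frameshift, in-frame
    deletion and splice). With zero synonymous mutations the ratio is
    reported as infinity with a warning.
    """
    counts = {k: int(counts.get(k, 0)) for k in _CODING_CLASSES}
    total = sum(counts.values())
    percentages = {k: _round_half_up(100.0 * v / total) if total else 0
                   for k, v in counts.items()}
    nonsyn = sum(counts[k] for k in NONSYNONYMOUS_CLASSES)
    syn = counts["synonymous"]
    if syn == 0:
        if nonsyn > 0:
            warnings.warn("no synonymous mutations; NS/S ratio undefined (inf)")
            ratio = float("inf")
        else:
            ratio = 0.0
    else:
        ratio = nonsyn / syn
    return {
        "counts": counts,
        "total_coding_splice": total,
        "percentages": percentages,
        "ns_s_ratio": round(ratio, 2) if math.isfinite(ratio) else ratio,
        "n_nonsynonymous_incl_splice": nonsyn,
        "n_nonsynonymous_excl_splice": nonsyn - counts["splice"],
    }


def class_distribution(calls: list[VariantCall]) -> dict:
    """Class summary over somatic calls in coding exons or splice sites."""
    counts: dict[str, int] = {}
    for call in calls:
        if call.status != "somatic":
            continue
        cls = call.site.consequence
        if cls in _CODING_CLASSES:
            counts[cls] = counts.get(cls, 0) + 1
    return class_distribution_from_counts(counts)


def gene_list_overlap(calls: list[VariantCall],
                      gene_list) -> tuple[int, int]:
    """Count non-synonymous/splice somatic mutations hitting genes in
    ``gene_list`` and the distinct genes hit. Symbols are matched
    case-insensitively after whitespace strip."""
    wanted = {g.strip().upper() for g in gene_list if g and g.strip()}
    n_mut = 0
    genes = set()
    for call in calls:
        if call.status != "somatic" or call.site.consequence not in NONSYNONYMOUS_CLASSES:
            continue
        g = call.site.gene.strip().upper()
        if g and g in wanted:
            n_mut += 1
            genes.add(g)
    return n_mut, len(genes)


def run_pipeline(config: synthetic.CohortConfig | None = None, seed: int = 0,
                 out_dir: str | None = None,
                 fdr_permutations: int = 300,
                 segmentation_permutations: int = 200) -> dict:
    """Run the full synthetic cohort workflow and return the report.

    Per patient: host-read filtering (xenografts), base-quality mixture
    filtering, somatic calling against the germline for both primary and
    model, primary-vs-model comparison with permutation FDR, contamination
    estimation, and CNA calling with concordance scoring. Cohort-wide, all
    tumor samples are clustered on high-confidence segment logR.
    Deterministic for a fixed (config, seed).
    """
    if config is None:
        config = synthetic.CohortConfig(seed=seed)
    cohort = synthetic.simulate_cohort(config)
    truth = cohort.truth
    report: dict = {"seed": seed, "patients": {}}
    cluster_inputs: dict[str, tuple] = {}

    for pdat in cohort.patients:
        pid = pdat.patient
        entry: dict = {"model_type": pdat.model_type, "log": []}
        sites = pdat.sites
        entry["log"].append({"stage": "input", "n_sites": len(sites)})

        # --- host-read removal (xenografts) -----------------------------
        if pdat.model_type == "xenograft" and pdat.reads:
            kept_ids, stats = xenofilter.filter_read_set(pdat.reads)
            kept = set(kept_ids)
            mouse_ids = [r.read_id for r in pdat.reads
                         if truth.read_species[(pid, r.read_id)] == "mouse"]
            retention = (sum(1 for r in mouse_ids if r in kept) / len(mouse_ids)
                         if mouse_ids else 0.0)
            n_before = _count_somatic(sites, "model")
            sites = synthetic.thin_mouse_support(sites, pid, truth, retention,
                                                 seed=config.seed + 1000 + pid)
            entry["xenofilter"] = {**stats, "mouse_read_retention": retention,
                                   "model_somatic_before": n_before,
                                   "model_somatic_after": _count_somatic(sites, "model")}
            entry["log"].append({"stage": "xenofilter", "reads_in": stats["total"],
                                 "reads_kept": stats["kept"]})

        # --- base-quality mixture filtering ------------------------------
        novel = [s for s in sites if not s.known]
        known = [s for s in sites if s.known]
        try:
            fit = quality.fit_quality_mixture([s.mean_alt_quality for s in novel],
                                              seed=config.seed + pid)
            kept_novel, discarded = quality.filter_variants_by_quality(
                novel, fit, exempt_known=False)
            entry["quality_filter"] = {
                "n_components": fit.n_components,
                "n_discarded": len(discarded),
            }
        except InsufficientDataError:
            # too few novel sites to model the quality distribution
            kept_novel, discarded = novel, []
            entry["quality_filter"] = {"n_components": None, "n_discarded": 0}
        sites = sorted(known + kept_novel,
                       key=lambda s: (cna._chrom_key(s.chrom), s.pos))
        entry["log"].append({"stage": "quality_filter", "in": len(novel) + len(known),
                             "out": len(sites)})

        # --- restrict to capture targets and call ------------------------
        targets = [(p.chrom, p.start, p.end) for p in pdat.probes["primary"]]
        # site coordinates are genome-wide in the simulation; call all sites
        primary_calls = calling.call_sites(sites, tumor_sample="primary")
        model_calls = calling.call_sites(sites, tumor_sample="model")
        somatic_primary = [c for c in primary_calls if c.status == "somatic"]
        somatic_model = [c for c in model_calls if c.status == "somatic"]
        entry["n_somatic_primary"] = len(somatic_primary)
        entry["n_somatic_model"] = len(somatic_model)
        entry["log"].append({"stage": "somatic_calling",
                             "primary": len(somatic_primary),
                             "model": len(somatic_model)})

        # --- CNA calling --------------------------------------------------
        het_sites = [s for s in sites
                     if truth.site_status.get((pid, s.chrom, s.pos)) == "germline_het"]
        seg_by_sample = {}
        for sample in ("primary", "model"):
            probes = cna.gc_correct(pdat.probes[sample])
            probes = cna.compute_logr(probes)
            segs = cna.segment(probes, seed=config.seed + 17 * (pid + 1),
                               n_permutations=segmentation_permutations)
            segs = cna.call_segments(segs, probes)
            segs = cna.call_loh(het_sites, segs, tumor_sample=sample)
            seg_by_sample[sample] = (segs, probes)
            cluster_inputs[f"P{pid}_{sample}"] = (segs, probes)
        arm_calls = cna.call_arms(seg_by_sample["primary"][0], cohort.cytobands())
        entry["arm_calls"] = [{"chrom": a.chrom, "arm": a.arm, "call": a.call}
                              for a in arm_calls if a.call != "neutral"]
        _table, consistent = cna.cna_concordance(
            seg_by_sample["primary"][0], seg_by_sample["model"][0], targets)
        entry["cna_consistent_fraction"] = consistent
        entry["log"].append({"stage": "cna", "consistent_fraction": consistent})

        # --- primary vs model comparison ---------------------------------
        union_sites = sorted({id(c.site): c.site
                              for c in somatic_primary + somatic_model}.values(),
                             key=lambda s: (cna._chrom_key(s.chrom), s.pos))
        if union_sites:
            records = comparison.build_records(union_sites)
            fdr = comparison.permutation_fdr(records, n_permutations=fdr_permutations,
                                             seed=config.seed + 31 * (pid + 1))
            records = comparison.classify_records(records, fdr)
            entry["comparison"] = {
                "p_threshold": fdr.p_threshold,
                "class_counts": comparison.class_counts(records),
            }
            try:
                r, n_used = comparison.maf_correlation(records)
                entry["comparison"]["maf_r"] = r
                entry["comparison"]["maf_n_used"] = n_used
            except InsufficientDataError:
                pass
            neutral_segs = [s for s in seg_by_sample["primary"][0]]
            try:
                c = comparison.estimate_contamination(records, neutral_segs)
                entry["contamination"] = c
            except InsufficientDataError:
                entry["contamination"] = None
            shared = [rec for rec in records
                      if rec.q_class in ("shared_constant", "shared_changing")]
            in_primary = [rec for rec in records if rec.q_class != "model_only"]
            entry["comparison"]["shared_fraction_of_primary"] = (
                len(shared) / len(in_primary) if in_primary else float("nan"))

        # --- mutational profile ------------------------------------------
        entry["profile"] = class_distribution(primary_calls)
        snv_calls = [c.site for c in primary_calls
                     if c.status in ("germline", "somatic") and c.site.variant_type == "snv"]
        entry["titv"] = quality.titv_ratio(snv_calls) if snv_calls else None
        germline_sites = [c.site for c in primary_calls if c.status == "germline"]
        entry["germline_known_fraction"] = (quality.known_fraction(germline_sites)
                                            if germline_sites else None)
        report["patients"][str(pid)] = entry

    # --- cohort relatedness ----------------------------------------------
    try:
        mat, names, _features = cna.hc_segment_logr_matrix(cluster_inputs)
        report["dendrogram"] = cna.cluster_samples(mat, names)
    except Exception as exc:  # no hc segments anywhere
        report["dendrogram"] = None
        report["dendrogram_error"] = str(exc)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        io.write_cohort(cohort, os.path.join(out_dir, "cohort"))
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _count_somatic(sites, tumor_sample: str) -> int:
    return sum(1 for c in calling.call_sites(sites, tumor_sample=tumor_sample)
               if c.status == "somatic")
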