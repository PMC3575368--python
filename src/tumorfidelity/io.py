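"""Readers and writers for the pipeline's on-disk formats.

Sites travel as TSV (primary interchange) and multi-sample VCF with AD-style
allele depths; reads as dual-alignment TSV; probes as TSV and BED (0-based
half-open); segments as SEG; chromosome arms as UCSC cytoBand-format TSV;
ground truth and summaries as JSON.
"""
from __future__ import annotations

import json
import os

import pandas as pd

from .types import (
    AlleleCount,
    CopySegment,
    ReadRecord,
    SiteObservation,
    TargetProbe,
    ValidationError,
)

SAMPLE_ROLES = ("germline", "primary", "model")


# ------------------------------------------------------------------- sites

def sites_to_frame(sites: list[SiteObservation]) -> pd.DataFrame:
    rows = []
    for s in sites:
        row = {
            "chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt,
            "variant_type": s.variant_type,
            "mean_alt_quality": s.mean_alt_quality,
            "consequence": s.consequence, "known": int(s.known), "gene": s.gene,
        }
        for role in SAMPLE_ROLES:
            ac = s.counts.get(role)
            row[f"{role}_ref"] = ac.ref_count if ac else ""
            row[f"{role}_alt"] = ac.alt_count if ac else ""
        rows.append(row)
    return pd.DataFrame(rows)


def write_sites_tsv(sites: list[SiteObservation], path: str) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str) -> list[SiteObservation]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str},
                     keep_default_na=False, na_values=[])
    sites = []
    for _, r in df.iterrows():
        counts = {}
        for role in SAMPLE_ROLES:
            ref, alt = r.get(f"{role}_ref", ""), r.get(f"{role}_alt", "")
            if ref != "" and alt != "":
                counts[role] = AlleleCount(int(ref), int(alt))
        sites.append(SiteObservation(
            chrom=str(r["chrom"]), pos=int(r["pos"]), ref=str(r["ref"]),
            alt=str(r["alt"]), variant_type=str(r["variant_type"]),
            counts=counts, mean_alt_quality=float(r["mean_alt_quality"]),
            consequence=str(r["consequence"]), known=bool(int(r["known"])),
            gene=str(r.get("gene", ""))))
    return sites


def write_sites_vcf(sites: list[SiteObservation], path: str,
                    contig_lengths: dict[str, int] | None = None) -> None:
    """Multi-sample VCF with per-sample AD (ref,alt depths)."""
    import pysam

    header = pysam.VariantHeader()
    contigs = contig_lengths or {}
    seen = {s.chrom for s in sites}
    for chrom in sorted(seen | set(contigs), key=lambda c: (len(c), c)):
        header.contigs.add(chrom, length=contigs.get(chrom, 2_000_000_000))
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.info.add("MAQ", 1, "Float", "Mean alternate-allele base quality")
    header.info.add("CSQCLS", 1, "String", "Consequence class")
    header.info.add("KNOWN", 0, "Flag", "Present in a known-variant database")
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("VT", 1, "String", "Variant type (snv/indel)")
    for role in SAMPLE_ROLES:
        header.add_sample(role)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for s in sorted(sites, key=lambda s: (s.chrom, s.pos)):
            rec = vcf.new_record(contig=s.chrom, start=s.pos - 1,
                                 alleles=(s.ref, s.alt))
            rec.info["MAQ"] = float(s.mean_alt_quality)
            rec.info["CSQCLS"] = s.consequence
            rec.info["VT"] = s.variant_type
            if s.known:
                rec.info["KNOWN"] = True
            if s.gene:
                rec.info["GENE"] = s.gene
            for role in SAMPLE_ROLES:
                ac = s.counts.get(role)
                if ac is not None:
                    rec.samples[role]["AD"] = (ac.ref_count, ac.alt_count)
            vcf.write(rec)


def read_sites_vcf(path: str) -> list[SiteObservation]:
    import pysam

    sites = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            counts = {}
            for role in SAMPLE_ROLES:
                if role in rec.samples:
                    ad = rec.samples[role].get("AD")
                    if ad is not None and ad[0] is not None:
                        counts[role] = AlleleCount(int(ad[0]), int(ad[1]))
            sites.append(SiteObservation(
                chrom=rec.contig, pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
                variant_type=rec.info.get("VT", "snv"),
                counts=counts,
                mean_alt_quality=float(rec.info.get("MAQ", float("nan"))),
                consequence=rec.info.get("CSQCLS", "noncoding"),
                known=bool(rec.info.get("KNOWN", False)),
                gene=rec.info.get("GENE", "") or ""))
    return sites


# ------------------------------------------------------------------- reads

READ_COLUMNS = ["read_id", "human_mapped", "human_proper_pair", "human_matches",
                "human_mismatches", "mouse_mapped", "mouse_proper_pair",
                "mouse_matches", "mouse_mismatches"]


def write_reads_tsv(reads: list[ReadRecord], path: str) -> None:
    rows = [{c: int(getattr(r, c)) if c != "read_id" else r.read_id
             for c in READ_COLUMNS} for r in reads]
    pd.DataFrame(rows, columns=READ_COLUMNS).to_csv(path, sep="\t", index=False)


def read_reads_tsv(path: str) -> list[ReadRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(READ_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"read TSV missing columns: {sorted(missing)}")
    return [ReadRecord(
        read_id=str(r.read_id),
        human_mapped=bool(r.human_mapped), human_proper_pair=bool(r.human_proper_pair),
        human_matches=int(r.human_matches), human_mismatches=int(r.human_mismatches),
        mouse_mapped=bool(r.mouse_mapped), mouse_proper_pair=bool(r.mouse_proper_pair),
        mouse_matches=int(r.mouse_matches), mouse_mismatches=int(r.mouse_mismatches))
        for r in df.itertuples(index=False)]


# ------------------------------------------------------------------- probes

def write_probes_tsv(probes: list[TargetProbe], path: str) -> None:
    rows = [{"chrom": p.chrom, "start": p.start, "end": p.end, "gc": p.gc,
             "normal_cov": p.normal_cov, "tumor_cov": p.tumor_cov,
             "logr": p.logr, "nc": int(p.nc)} for p in probes]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_probes_tsv(path: str) -> list[TargetProbe]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [TargetProbe(chrom=str(r.chrom), start=int(r.start), end=int(r.end),
                        gc=float(r.gc), normal_cov=float(r.normal_cov),
                        tumor_cov=float(r.tumor_cov), logr=float(r.logr),
                        nc=bool(int(r.nc)))
            for r in df.itertuples(index=False)]


def write_bed(intervals: list[tuple[str, int, int]], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed(path: str) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


# ------------------------------------------------------------------- cytobands

def write_cytobands(rows: list[tuple[str, int, int, str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, band, stain in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{band}\t{stain}\n")


def read_cytobands(path: str) -> list[tuple[str, int, int, str, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 5:
                continue
            out.append((f[0], int(f[1]), int(f[2]), f[3], f[4]))
    return out


# ------------------------------------------------------------------- segments

def write_segments_seg(segments: list[CopySegment], sample: str, path: str) -> None:
    """SEG format plus call/confidence/loh columns."""
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tn_probes\tmean_logr\tcall\tconfidence\tloh\n")
        for s in segments:
            fh.write(f"{sample}\t{s.chrom}\t{s.start}\t{s.end}\t{s.n_probes}\t"
                     f"{s.mean_logr:.6g}\t{s.call}\t{s.confidence}\t{int(s.loh)}\n")


def read_segments_seg(path: str) -> list[CopySegment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [CopySegment(chrom=str(r.chrom), start=int(r.start), end=int(r.end),
                        mean_logr=float(r.mean_logr), n_probes=int(r.n_probes),
                        call=str(r.call), confidence=str(r.confidence),
                        loh=bool(int(r.loh)))
            for r in df.itertuples(index=False)]


# ------------------------------------------------------------------- cohort

def write_truth_json(truth, path: str) -> None:
    payload = {
        "site_status": {f"{p}:{c}:{pos}": v
                        for (p, c, pos), v in truth.site_status.items()},
        "site_ccf": {f"{p}:{c}:{pos}": (None if v != v else v)
                     for (p, c, pos), v in truth.site_ccf.items()},
        "mouse_alt_support": {f"{p}:{c}:{pos}:{s}": v
                              for (p, c, pos, s), v in truth.mouse_alt_support.items()},
        "sample_purity": {f"{p}:{s}": v for (p, s), v in truth.sample_purity.items()},
        "read_species": {f"{p}:{r}": v for (p, r), v in truth.read_species.items()},
        "copy_number": {str(p): v for p, v in truth.copy_number.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def write_cohort(cohort, out_dir: str) -> None:
    """Serialize a synthetic cohort: per-patient site TSV+VCF, read TSV,
    probe TSV/BED, plus cohort-level cytoband TSV and truth JSON."""
    os.makedirs(out_dir, exist_ok=True)
    contigs = {f"chr{i}": cohort.config.chrom_length
               for i in range(1, cohort.config.n_chromosomes + 1)}
    for pd_ in cohort.patients:
        tag = f"patient{pd_.patient}"
        write_sites_tsv(pd_.sites, os.path.join(out_dir, f"{tag}.sites.tsv"))
        write_sites_vcf(pd_.sites, os.path.join(out_dir, f"{tag}.sites.vcf"),
                        contig_lengths=contigs)
        if pd_.reads:
            write_reads_tsv(pd_.reads, os.path.join(out_dir, f"{tag}.reads.tsv"))
        for sample, probes in pd_.probes.items():
            write_probes_tsv(probes, os.path.join(out_dir, f"{tag}.{sample}.probes.tsv"))
            write_bed([(p.chrom, p.start, p.end) for p in probes],
                      os.path.join(out_dir, f"{tag}.{sample}.probes.bed"))
    write_cytobands(cohort.cytobands(), os.path.join(out_dir, "cytobands.tsv"))
    write_truth_json(cohort.truth, os.path.join(out_dir, "truth.json"))
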