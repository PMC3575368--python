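"""Xenograft host-read removal.

Tumors grown in mouse flanks yield sequencing libraries contaminated by
murine DNA; mouse reads captured and aligned to the human reference inflate
apparent somatic mutation counts, especially at strongly orthologous genes.
Each read is aligned to both genomes and assigned to its most likely species
by a filter cascade: mapping status, then proper pairing, then the match
score M = matches - mismatches. Only reads called human are kept; mouse and
ambiguous reads are dropped.
"""
from __future__ import annotations

from collections import Counter

from .types import ReadRecord, SpeciesCall, ValidationError


def match_score(matches: int, mismatches: int) -> int:
    """Alignment match score M = matches - mismatches (may be negative)."""
    if matches < 0 or mismatches < 0:
        raise ValidationError("matches and mismatches must be non-negative")
    return matches - mismatches


def classify_read(rec: ReadRecord) -> SpeciesCall:
    """Assign a read to human, mouse, or ambiguous.

    Cascade: (1) mapped to only one genome -> that genome; (2) both mapped
    and proper-pairing differs -> the properly paired genome; (3) pairing
    tied -> the strictly greater match score; (4) exact tie -> ambiguous.
    Ties are read strictly ("better alignment"), so orthologous regions that
    align equally well to both genomes are conservatively discarded.
    """
    if not rec.human_mapped and not rec.mouse_mapped:
        raise ValidationError(f"read {rec.read_id} mapped to neither genome")
    if rec.human_mapped and not rec.mouse_mapped:
        return SpeciesCall(rec.read_id, "human", "mapping")
    if rec.mouse_mapped and not rec.human_mapped:
        return SpeciesCall(rec.read_id, "mouse", "mapping")
    if rec.human_proper_pair != rec.mouse_proper_pair:
        call = "human" if rec.human_proper_pair else "mouse"
        return SpeciesCall(rec.read_id, call, "pairing")
    m_h = match_score(rec.human_matches, rec.human_mismatches)
    m_m = match_score(rec.mouse_matches, rec.mouse_mismatches)
    if m_h > m_m:
        return SpeciesCall(rec.read_id, "human", "match_score")
    if m_m > m_h:
        return SpeciesCall(rec.read_id, "mouse", "match_score")
    return SpeciesCall(rec.read_id, "ambiguous", "tie")


def filter_read_set(reads: list[ReadRecord]) -> tuple[list[str], dict]:
    """Classify every read and keep the human calls.

    Returns
    -------
    kept_ids : list of str
        Read ids called human, in input order.
    stats : dict
        ``{"total", "by_call": {...}, "by_reason": {...}}``; call counts
        sum to the input size.
    """
    kept = []
    by_call: Counter = Counter()
    by_reason: Counter = Counter()
    for rec in reads:
        sc = classify_read(rec)
        by_call[sc.call] += 1
        by_reason[sc.reason] += 1
        if sc.call == "human":
            kept.append(sc.read_id)
    stats = {
        "total": len(reads),
        "kept": len(kept),
        "by_call": {k: by_call.get(k, 0) for k in ("human", "mouse", "ambiguous")},
        "by_reason": dict(by_reason),
    }
    return kept, stats


def reads_from_dual_sam(human_path: str, mouse_path: str) -> list[ReadRecord]:
    """Build dual-genome read records from two SAM/BAM files.

    Matches are taken as aligned M/=/X bases minus the NM edit distance,
    mismatches as NM (the portable mismatch field). A read absent from one
    file is treated as unmapped against that genome.
    """
    import pysam

    def load(path):
        out = {}
        with pysam.AlignmentFile(path, check_sq=False) as fh:
            for aln in fh:
                if aln.is_secondary or aln.is_supplementary:
                    continue
                if aln.is_unmapped:
                    out.setdefault(aln.query_name, None)
                    continue
                aligned = sum(n for op, n in (aln.cigartuples or ())
                              if op in (0, 7, 8))  # M, =, X
                nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
                out[aln.query_name] = (max(aligned - nm, 0), nm, aln.is_proper_pair)
        return out

    human = load(human_path)
    mouse = load(mouse_path)
    records = []
    for rid in sorted(set(human) | set(mouse)):
        h = human.get(rid)
        m = mouse.get(rid)
        records.append(ReadRecord(
            read_id=rid,
            human_mapped=h is not None,
            human_proper_pair=bool(h[2]) if h else False,
            human_matches=h[0] if h else 0,
            human_mismatches=h[1] if h else 0,
            mouse_mapped=m is not None,
            mouse_proper_pair=bool(m[2]) if m else False,
            mouse_matches=m[0] if m else 0,
            mouse_mismatches=m[1] if m else 0))
    return records
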