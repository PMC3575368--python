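"""Exome-based copy-number aberration calling and concordance scoring.

Per-probe tumor/normal coverage ratios (logR), corrected for GC-content
bias, are segmented by recursive binary splitting with a permutation test
(circular-binary-segmentation style). Segments are called amplified,
deleted, or neutral against a logR band, graded high-confidence when their
mean logR clears the 95th (amplification) or 5th (deletion) percentile of
the copy-neutral probes' logR distribution, aggregated into chromosome-arm
calls (>20% of an arm's targeted base pairs consistently aberrant), flagged
for loss of heterozygosity from germline-het allele balance, and compared
between primary and model at base-pair resolution. Sample relatedness is
summarized by average-linkage hierarchical clustering on high-confidence
segment logR.
"""
from __future__ import annotations

import warnings

import numpy as np

from .types import (
    CopySegment,
    ArmCall,
    SiteObservation,
    TargetProbe,
    ValidationError,
)


# ---------------------------------------------------------------- GC correction

def gc_correct(probes: list[TargetProbe], bin_width: float = 0.01,
               min_bin_size: int = 10) -> list[TargetProbe]:
    """Remove GC-content coverage bias by median scaling within GC bins.

    Per sample, each probe's coverage is divided by the median coverage of
    its GC bin and multiplied by the global median, so bins with unbiased
    coverage are (nearly) unchanged. Bins holding fewer than
    ``min_bin_size`` probes are merged with their neighbors. Returns new
    probe objects.
    """
    if not probes:
        return []
    gc = np.array([p.gc for p in probes])
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    idx = np.clip(np.digitize(gc, edges) - 1, 0, len(edges) - 2)
    # merge sparse bins left-to-right so each kept bin has >= min_bin_size
    order = np.unique(idx)
    merged: dict[int, int] = {}
    group: list[int] = []
    count = 0
    groups: list[list[int]] = []
    for b in order:
        group.append(b)
        count += int((idx == b).sum())
        if count >= min_bin_size:
            groups.append(group)
            group, count = [], 0
    if group:
        if groups:
            groups[-1].extend(group)
        else:
            groups.append(group)
    for gi, g in enumerate(groups):
        for b in g:
            merged[b] = gi
    gidx = np.array([merged[b] for b in idx])

    out = []
    cols = {}
    for attr in ("normal_cov", "tumor_cov"):
        cov = np.array([getattr(p, attr) for p in probes], dtype=float)
        global_med = np.median(cov)
        corrected = cov.copy()
        for gi in np.unique(gidx):
            mask = gidx == gi
            med = np.median(cov[mask])
            if med > 0:
                corrected[mask] = cov[mask] / med * global_med
        cols[attr] = corrected
    for i, p in enumerate(probes):
        out.append(TargetProbe(chrom=p.chrom, start=p.start, end=p.end, gc=p.gc,
                               normal_cov=float(cols["normal_cov"][i]),
                               tumor_cov=float(cols["tumor_cov"][i]),
                               logr=p.logr, nc=p.nc))
    return out


def compute_logr(probes: list[TargetProbe], min_normal_cov: float = 10.0
                 ) -> list[TargetProbe]:
    """Set per-probe logR = log2 of library-size-normalized tumor/normal
    coverage; probes with normal coverage below ``min_normal_cov`` are
    marked not-callable (nc) with undefined logR."""
    if not probes:
        return []
    t_tot = sum(p.tumor_cov for p in probes)
    n_tot = sum(p.normal_cov for p in probes)
    if t_tot <= 0 or n_tot <= 0:
        raise ValidationError("total coverage must be positive to compute logR")
    out = []
    for p in probes:
        nc = p.normal_cov < min_normal_cov
        if nc or p.tumor_cov <= 0:
            logr = float("nan")
            nc = True
        else:
            logr = float(np.log2((p.tumor_cov / t_tot) / (p.normal_cov / n_tot)))
        out.append(TargetProbe(chrom=p.chrom, start=p.start, end=p.end, gc=p.gc,
                               normal_cov=p.normal_cov, tumor_cov=p.tumor_cov,
                               logr=logr, nc=nc))
    return out


# ---------------------------------------------------------------- segmentation

def _split_stat(x: np.ndarray) -> tuple[int, float]:
    """Best split index (left size) and its |t| statistic."""
    n = x.size
    cs = np.cumsum(x)
    cs2 = np.cumsum(x * x)
    n1 = np.arange(1, n)
    n2 = n - n1
    m1 = cs[:-1] / n1
    m2 = (cs[-1] - cs[:-1]) / n2
    ss = cs2[-1] - n1 * m1 ** 2 - n2 * m2 ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = np.sqrt(np.maximum(ss, 0.0) / np.maximum(n - 2, 1))
        t = np.abs(m1 - m2) / (pooled * np.sqrt(1.0 / n1 + 1.0 / n2))
    t[~np.isfinite(t)] = 0.0
    i = int(np.argmax(t))
    return i + 1, float(t[i])


def _segment_chrom(x: np.ndarray, alpha: float, rng: np.random.Generator,
                   n_permutations: int, min_probes: int) -> list[tuple[int, int]]:
    """Recursive binary splitting; returns [start, end) probe-index spans."""
    def recurse(lo: int, hi: int, out: list):
        n = hi - lo
        if n < min_probes:
            out.append((lo, hi))
            return
        seg = x[lo:hi]
        split, t_obs = _split_stat(seg)
        if t_obs <= 0:
            out.append((lo, hi))
            return
        null = np.empty(n_permutations)
        for j in range(n_permutations):
            null[j] = _split_stat(rng.permutation(seg))[1]
        p = (1.0 + float((null >= t_obs).sum())) / (1.0 + n_permutations)
        if p <= alpha:
            recurse(lo, lo + split, out)
            recurse(lo + split, hi, out)
        else:
            out.append((lo, hi))

    spans: list[tuple[int, int]] = []
    recurse(0, x.size, spans)
    return spans


def segment(probes: list[TargetProbe], alpha: float = 0.01, seed: int = 0,
            n_permutations: int = 1000, min_probes: int = 5) -> list[CopySegment]:
    """Segment per-probe logR into runs of constant copy number.

    Within each chromosome, the probe sequence is recursively split at the
    position maximizing the two-sample t statistic of mean logR; a split is
    accepted when its permutation p-value is at or below ``alpha``.
    Not-callable probes take the chromosome median logR during segmentation
    (they cannot create breakpoints) but stay flagged for concordance.
    Chromosomes with fewer than ``min_probes`` probes form one untested
    segment.
    """
    rng = np.random.default_rng(seed)
    segments: list[CopySegment] = []
    chroms: dict[str, list[TargetProbe]] = {}
    for p in probes:
        chroms.setdefault(p.chrom, []).append(p)
    for chrom in chroms:
        ps = sorted(chroms[chrom], key=lambda p: p.start)
        x = np.array([p.logr for p in ps], dtype=float)
        finite = np.isfinite(x)
        fill = float(np.median(x[finite])) if finite.any() else 0.0
        x[~finite] = fill
        for lo, hi in _segment_chrom(x, alpha, rng, n_permutations, min_probes):
            sub = [p for p in ps[lo:hi]]
            vals = [p.logr for p in sub if np.isfinite(p.logr)]
            n_nc = sum(1 for p in sub if p.nc)
            mean_logr = float(np.mean(vals)) if vals else float("nan")
            seg = CopySegment(chrom=chrom, start=sub[0].start, end=sub[-1].end,
                              mean_logr=mean_logr, n_probes=len(sub))
            if n_nc > len(sub) / 2:
                seg.call = "nc"
            segments.append(seg)
    segments.sort(key=lambda s: (_chrom_key(s.chrom), s.start))
    return segments


def _chrom_key(chrom: str):
    c = chrom.replace("chr", "")
    return (0, int(c)) if c.isdigit() else (1, c)


# ---------------------------------------------------------------- state calling

def call_segments(segments: list[CopySegment], probes: list[TargetProbe],
                  neutral_band: float = 0.2) -> list[CopySegment]:
    """Assign amp/del/neutral calls and grade high-confidence segments.

    A segment is neutral when |mean logR| <= ``neutral_band``, otherwise
    amp/del by sign. High-confidence (hc): mean logR above the 95th
    percentile (amp) or below the 5th (del) of the per-probe logR
    distribution within neutral segments. Without any neutral segment the
    hc grade is skipped with a warning. Segments are updated in place and
    returned.
    """
    neutral_spans = []
    for seg in segments:
        if seg.call == "nc":
            seg.confidence = "standard"
            continue
        if abs(seg.mean_logr) <= neutral_band:
            seg.call = "neutral"
            neutral_spans.append(seg)
        else:
            seg.call = "amp" if seg.mean_logr > 0 else "del"
    neutral_logr = [p.logr for p in probes if np.isfinite(p.logr)
                    and any(s.chrom == p.chrom and s.start <= p.start < s.end
                            for s in neutral_spans)]
    if not neutral_logr:
        warnings.warn("no copy-neutral segments; high-confidence grading skipped")
        return segments
    lo, hi = np.percentile(neutral_logr, [5.0, 95.0])
    for seg in segments:
        if seg.call == "amp" and seg.mean_logr > hi:
            seg.confidence = "hc"
        elif seg.call == "del" and seg.mean_logr < lo:
            seg.confidence = "hc"
        else:
            seg.confidence = "standard"
    return segments


def call_arms(segments: list[CopySegment],
              cytobands: list[tuple[str, int, int, str, str]],
              threshold: float = 0.20) -> list[ArmCall]:
    """Arm-level CNA calls: an arm is amp/del when more than ``threshold``
    of its targeted base pairs lie in segments consistently called in that
    direction (mixed directions count separately; if both exceed, the
    larger wins)."""
    arms: dict[tuple[str, str], tuple[int, int]] = {}
    for chrom, start, end, band, _stain in cytobands:
        arm = band[0]
        if arm not in ("p", "q"):
            continue
        key = (chrom, arm)
        if key in arms:
            s, e = arms[key]
            arms[key] = (min(s, start), max(e, end))
        else:
            arms[key] = (start, end)

    out = []
    for (chrom, arm), (a_start, a_end) in sorted(arms.items(),
                                                 key=lambda kv: (_chrom_key(kv[0][0]), kv[0][1])):
        total = amp = dele = 0
        for seg in segments:
            if seg.chrom != chrom:
                continue
            ov = min(seg.end, a_end) - max(seg.start, a_start)
            if ov <= 0:
                continue
            total += ov
            if seg.call == "amp":
                amp += ov
            elif seg.call == "del":
                dele += ov
        if total == 0:
            continue
        f_amp, f_del = amp / total, dele / total
        if f_amp > threshold and f_amp >= f_del:
            call = "amp"
        elif f_del > threshold:
            call = "del"
        else:
            call = "neutral"
        out.append(ArmCall(chrom=chrom, arm=arm, call=call,
                           fraction_bp_amp=f_amp, fraction_bp_del=f_del))
    return out


def call_loh(het_sites: list[SiteObservation], segments: list[CopySegment],
             tumor_sample: str = "primary", min_sites: int = 10,
             min_departure: float = 0.2) -> list[CopySegment]:
    """Flag segments showing loss of heterozygosity: at least ``min_sites``
    germline-het sites inside the segment whose median tumor alt fraction
    departs from 0.5 by at least ``min_departure``. Updates in place."""
    for seg in segments:
        bafs = [s.counts[tumor_sample].alt_fraction for s in het_sites
                if s.chrom == seg.chrom and seg.start < s.pos <= seg.end
                and s.counts[tumor_sample].depth > 0]
        seg.loh = (len(bafs) >= min_sites
                   and abs(float(np.median(bafs)) - 0.5) >= min_departure)
    return segments


# ---------------------------------------------------------------- concordance

def _call_at(segments_by_chrom, chrom: str, lo: int, hi: int):
    """Yield (piece_lo, piece_hi, call) over [lo, hi) from a sample's
    disjoint segment list; uncovered gaps are 'nc'."""
    pos = lo
    for seg in segments_by_chrom.get(chrom, ()):
        if seg.end <= pos or seg.start >= hi:
            continue
        if seg.start > pos:
            yield pos, seg.start, "nc"
            pos = seg.start
        e = min(seg.end, hi)
        yield pos, e, seg.call
        pos = e
        if pos >= hi:
            break
    if pos < hi:
        yield pos, hi, "nc"


def cna_concordance(primary_segments: list[CopySegment],
                    model_segments: list[CopySegment],
                    targets: list[tuple[str, int, int]]
                    ) -> tuple[dict[tuple[str, str], int], float]:
    """Base-pair level concordance of copy-number calls over targeted DNA
    inside high-confidence segments of either sample.

    Returns the (primary call, model call) bp contingency over
    {amp, del, neutral, nc} and the consistent fraction: diagonal bp
    (amp/del/neutral only) over all bp where neither call is nc.
    """
    def index(segs):
        d: dict[str, list[CopySegment]] = {}
        for s in segs:
            d.setdefault(s.chrom, []).append(s)
        for v in d.values():
            v.sort(key=lambda s: s.start)
        return d

    p_idx, m_idx = index(primary_segments), index(model_segments)
    hc: dict[str, list[tuple[int, int]]] = {}
    for s in list(primary_segments) + list(model_segments):
        if s.confidence == "hc":
            hc.setdefault(s.chrom, []).append((s.start, s.end))
    # merge hc regions per chromosome
    for chrom in hc:
        ivs = sorted(hc[chrom])
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        hc[chrom] = [(s, e) for s, e in merged]

    states = ("amp", "del", "neutral", "nc")
    table = {(a, b): 0 for a in states for b in states}
    for chrom, t_start, t_end in targets:
        for r_start, r_end in hc.get(chrom, ()):
            lo, hi = max(t_start, r_start), min(t_end, r_end)
            if lo >= hi:
                continue
            for p_lo, p_hi, p_call in _call_at(p_idx, chrom, lo, hi):
                for m_lo, m_hi, m_call in _call_at(m_idx, chrom, p_lo, p_hi):
                    table[(p_call, m_call)] += m_hi - m_lo
    classified = sum(v for (a, b), v in table.items() if a != "nc" and b != "nc")
    agree = sum(table[(s, s)] for s in ("amp", "del", "neutral"))
    fraction = agree / classified if classified > 0 else float("nan")
    return table, fraction


# ---------------------------------------------------------------- relatedness

def hc_segment_logr_matrix(samples: dict[str, tuple[list[CopySegment], list[TargetProbe]]]
                           ) -> tuple[np.ndarray, list[str], list[tuple[str, int, int]]]:
    """Feature matrix for clustering: rows are samples (sorted by name),
    columns are the merged union of high-confidence segments across samples,
    entries the sample's mean probe logR within the feature (0 where the
    sample has no callable probe)."""
    regions: dict[str, list[tuple[int, int]]] = {}
    for segs, _probes in samples.values():
        for s in segs:
            if s.confidence == "hc":
                regions.setdefault(s.chrom, []).append((s.start, s.end))
    features: list[tuple[str, int, int]] = []
    for chrom in sorted(regions, key=_chrom_key):
        ivs = sorted(regions[chrom])
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        features.extend((chrom, s, e) for s, e in merged)
    if not features:
        raise ValidationError("no high-confidence segments in any sample")
    names = sorted(samples)
    mat = np.zeros((len(names), len(features)))
    for i, name in enumerate(names):
        _segs, probes = samples[name]
        for j, (chrom, s, e) in enumerate(features):
            vals = [p.logr for p in probes
                    if p.chrom == chrom and s <= p.start < e and np.isfinite(p.logr)]
            mat[i, j] = float(np.mean(vals)) if vals else 0.0
    return mat, names, features


def cluster_samples(logr_matrix: np.ndarray, names: list[str]) -> str:
    """Average-linkage hierarchical clustering on Euclidean distances;
    returns a newick string with branch lengths. Deterministic: samples are
    processed in lexicographic name order."""
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import pdist

    mat = np.asarray(logr_matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != len(names):
        raise ValidationError("logr_matrix rows must match names")
    if len(names) == 1:
        return f"{names[0]};"
    order = np.argsort(names)
    names = [names[i] for i in order]
    mat = mat[order]
    Z = linkage(pdist(mat, metric="euclidean"), method="average")
    n = len(names)
    heights = {i: 0.0 for i in range(n)}

    def render(node: int) -> str:
        if node < n:
            return names[node]
        a, b, h, _cnt = Z[node - n]
        a, b = int(a), int(b)
        return (f"({render(a)}:{h - heights[a]:.6g},"
                f"{render(b)}:{h - heights[b]:.6g})")

    for k, row in enumerate(Z):
        heights[n + k] = float(row[2])
    return render(2 * n - 2) + ";"


def plot_logr(probes: list[TargetProbe], segments: list[CopySegment], path: str):
    """Simple per-chromosome logR scatter with segment means overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted({p.chrom for p in probes}, key=_chrom_key)
    offsets = {}
    x0 = 0
    for c in chroms:
        offsets[c] = x0
        x0 += max(p.end for p in probes if p.chrom == c)
    fig, ax = plt.subplots(figsize=(14, 3))
    xs = [offsets[p.chrom] + p.start for p in probes]
    ys = [p.logr for p in probes]
    ax.plot(xs, ys, ".", ms=2, color="0.6")
    for s in segments:
        color = {"amp": "red", "del": "blue"}.get(s.call, "black")
        ax.plot([offsets[s.chrom] + s.start, offsets[s.chrom] + s.end],
                [s.mean_logr, s.mean_logr], color=color, lw=2)
    ax.set_ylabel("logR")
    ax.set_xlabel("genome position")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
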