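"""Synthetic matched-cohort generator.

Emulates the statistical structure of a small exome-sequenced cohort of
primary tumors with matched pre-clinical models (neurosphere culture,
adherent culture, or mouse xenograft): binomial allele counts at ~60x mean
on-target depth, purity dilution of mutant allele frequencies, GC-biased
negative-binomial probe coverage carrying arm-level and focal copy-number
events, bimodal alternate-allele base qualities (true calls vs sequencing
artifacts), and murine read contamination in xenograft samples.

Every emitted site, read, and probe is covered by a :class:`GroundTruth`
record so downstream stages can be tested by parameter recovery.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .types import (
    AlleleCount,
    ConfigurationError,
    ReadRecord,
    SiteObservation,
    TargetProbe,
)

# toy genome: 22 chromosomes, two arms each
DEFAULT_N_CHROMOSOMES = 22
DEFAULT_CHROM_LENGTH = 10_000_000
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_BASES = "ACGT"

_CONSEQUENCE_PROBS = {
    "missense": 0.50,
    "nonsense": 0.026,
    "frameshift": 0.007,
    "inframe_deletion": 0.002,
    "splice": 0.011,
    "synonymous": 0.275,
    "noncoding": 0.179,
}


@dataclass(frozen=True)
class CnaEvent:
    """A copy-number event. ``start``/``end`` of ``None`` means whole
    chromosome; ``arm`` of "p"/"q" restricts to one arm."""

    chrom: str
    copy_number: int
    start: Optional[int] = None
    end: Optional[int] = None
    arm: Optional[str] = None


@dataclass
class CohortConfig:
    """Generative settings for one simulated cohort.

    Defaults reflect a four-patient glioblastoma-style cohort: ~60x mean
    on-target coverage, primary purities spanning 0.59-0.91 against
    effectively pure models, and 0-60% murine read contamination in the
    xenografted patients.
    """

    n_patients: int = 4
    model_types: tuple[str, ...] = ("neurosphere", "adherent", "xenograft", "xenograft")
    n_somatic_sites: int = 150
    n_germline_sites: int = 500
    mean_depth: float = 60.0
    primary_purities: tuple[float, ...] = (0.91, 0.89, 0.75, 0.59)
    model_purities: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    mouse_read_fractions: tuple[float, ...] = (0.0, 0.0, 0.3, 0.6)
    subclone_fractions: tuple[float, ...] = (1.0, 0.4)
    subclone_weights: tuple[float, ...] = (0.7, 0.3)
    artifact_fraction: float = 0.10
    quality_means: tuple[float, float] = (30.0, 12.0)  # (mu_true, mu_artifact)
    quality_sd: float = 2.0
    cna_events: Optional[dict[int, tuple[CnaEvent, ...]]] = None
    gc_bias_strength: float = 0.5
    # tumor libraries carry a stronger GC bow peaking at a shifted optimum
    # (separate capture/library batches), so logR retains a GC trend until
    # corrected
    gc_bias_tumor_factor: float = 1.6
    gc_bias_tumor_peak: float = 0.57
    nb_dispersion: float = 5.0  # site-level read depth (size parameter)
    # probe "coverage" is a fragment count pooled over the whole interval
    # (~4 fragments per unit depth at 200 bp probes / 50 bp reads), so its
    # relative noise is far smaller than single-position depth; size chosen
    # to give per-probe logR noise near 0.1
    probe_nb_size: float = 300.0
    n_reads: int = 20_000
    read_length: int = 50
    known_germline_fraction: float = 0.9
    ts_probability: float = 0.756  # transition share giving Ts/Tv ~ 3.1
    indel_fraction: float = 0.05
    base_error_rate: float = 0.002
    probes_per_chrom: int = 60
    n_chromosomes: int = DEFAULT_N_CHROMOSOMES
    chrom_length: int = DEFAULT_CHROM_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        for name in ("model_types", "primary_purities", "model_purities",
                     "mouse_read_fractions"):
            if len(getattr(self, name)) != self.n_patients:
                raise ConfigurationError(
                    f"{name} must have one entry per patient (n_patients={self.n_patients})")
        for t in self.model_types:
            if t not in ("neurosphere", "adherent", "xenograft"):
                raise ConfigurationError(f"model_types: unknown model type {t!r}")
        if self.mean_depth <= 0:
            raise ConfigurationError("mean_depth must be > 0")
        for name in ("primary_purities", "model_purities", "mouse_read_fractions"):
            for v in getattr(self, name):
                if not 0.0 <= v <= 1.0:
                    raise ConfigurationError(f"{name}: value {v} outside [0,1]")
        if not 0.0 <= self.artifact_fraction <= 1.0:
            raise ConfigurationError("artifact_fraction must be in [0,1]")
        for f in self.subclone_fractions:
            if not 0.0 < f <= 1.0:
                raise ConfigurationError("subclone_fractions must lie in (0,1]")
        if abs(sum(self.subclone_weights) - 1.0) > 1e-9:
            raise ConfigurationError("subclone_weights must sum to 1")
        mu_true, mu_art = self.quality_means
        if not mu_true > mu_art:
            raise ConfigurationError("quality_means: mu_true must exceed mu_artifact")
        if self.cna_events is not None:
            for pid, events in self.cna_events.items():
                if not 0 <= pid < self.n_patients:
                    raise ConfigurationError(f"cna_events: unknown patient index {pid}")
                for ev in events:
                    self._check_event(ev)

    def _check_event(self, ev: CnaEvent) -> None:
        idx = int(ev.chrom.replace("chr", ""))
        if not 1 <= idx <= self.n_chromosomes:
            raise ConfigurationError(f"cna_events: chromosome {ev.chrom} outside toy genome")
        if ev.start is not None and not (0 <= ev.start < ev.end <= self.chrom_length):
            raise ConfigurationError(
                f"cna_events: interval {ev.chrom}:{ev.start}-{ev.end} outside chromosome")
        if ev.copy_number < 0:
            raise ConfigurationError("cna_events: copy_number must be >= 0")


def default_cna_profiles(config: CohortConfig) -> dict[int, tuple[CnaEvent, ...]]:
    """Distinct per-patient CNA profiles: all patients share chr7 gain and
    chr10 loss (the classic glioblastoma pattern); each adds private events."""
    private = [
        (CnaEvent("chr5", 1, start=4_000_000, end=4_400_000),   # focal deletion
         CnaEvent("chr15", 1, arm="q"), CnaEvent("chr17", 1, arm="p")),
        (CnaEvent("chr13", 1, arm="q"), CnaEvent("chr6", 1, arm="q"),
         CnaEvent("chr4", 1, arm="q")),
        (CnaEvent("chr19", 3), CnaEvent("chr2", 3, arm="p"),
         CnaEvent("chr9", 1, arm="p")),
        (CnaEvent("chr12", 1, arm="p"), CnaEvent("chr14", 1, arm="q"),
         CnaEvent("chr18", 1, arm="q")),
    ]
    profiles: dict[int, tuple[CnaEvent, ...]] = {}
    for pid in range(config.n_patients):
        base = (CnaEvent("chr7", 3), CnaEvent("chr10", 1))
        profiles[pid] = base + private[pid % len(private)]
    return profiles


@dataclass
class GroundTruth:
    """Exhaustive truth labels for one simulated cohort."""

    # (patient, chrom, pos) -> status in {germline_het, germline_hom,
    #   somatic_clonal, somatic_subclonal, artifact, mouse_artifact}
    site_status: dict[tuple[int, str, int], str] = field(default_factory=dict)
    site_ccf: dict[tuple[int, str, int], float] = field(default_factory=dict)
    # (patient, chrom, pos, sample) -> alt reads attributable to murine DNA
    mouse_alt_support: dict[tuple[int, str, int, str], int] = field(default_factory=dict)
    # (patient, sample) -> purity
    sample_purity: dict[tuple[int, str], float] = field(default_factory=dict)
    # (patient, read_id) -> species
    read_species: dict[tuple[int, str], str] = field(default_factory=dict)
    # patient -> list of (chrom, start, end, copy_number); unlisted spans are CN 2
    copy_number: dict[int, list[tuple[str, int, int, int]]] = field(default_factory=dict)

    def status_of(self, patient: int, site: SiteObservation) -> str:
        return self.site_status[(patient, site.chrom, site.pos)]


@dataclass
class PatientData:
    patient: int
    model_type: str
    sites: list[SiteObservation]
    reads: list[ReadRecord]
    # sample role ("primary" | "model") -> probe list (normal_cov shared)
    probes: dict[str, list[TargetProbe]]


@dataclass
class Cohort:
    config: CohortConfig
    patients: list[PatientData]
    truth: GroundTruth

    def cytobands(self) -> list[tuple[str, int, int, str, str]]:
        """UCSC cytoBand-format rows for the toy genome (one p and one q
        band per chromosome, split at the midpoint)."""
        rows = []
        mid = self.config.chrom_length // 2
        for i in range(1, self.config.n_chromosomes + 1):
            chrom = f"chr{i}"
            rows.append((chrom, 0, mid, "p11", "gneg"))
            rows.append((chrom, mid, self.config.chrom_length, "q11", "gneg"))
        return rows


def expected_alt_fraction(m: int, ccf: float, purity: float, cn_t: int) -> float:
    """Expected mutant allele fraction of a somatic variant.

    f = m * CCF * p / (CN_t * p + 2 * (1 - p)) with ``m`` mutant copies,
    cancer-cell fraction ``ccf``, sample purity ``p`` and tumor copy number
    ``cn_t`` at the locus (normal cells contribute two reference copies).
    """
    denom = cn_t * purity + 2.0 * (1.0 - purity)
    if denom <= 0:
        return 0.0
    return m * ccf * purity / denom


def gc_coverage_factor(gc: np.ndarray | float, strength: float,
                       peak: float = 0.45) -> np.ndarray | float:
    """Smooth multiplicative coverage bias, a downward quadratic in GC
    peaking at ``peak``; ``strength`` 0 disables the bias."""
    g = 1.0 - strength * ((np.asarray(gc, dtype=float) - peak) ** 2) / 0.3025
    return np.maximum(g, 0.05)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray | float, dispersion: float):
    """Negative binomial with target mean and fixed dispersion (size)."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


class _CopyNumberMap:
    """Per-patient piecewise-constant copy number over the toy genome."""

    def __init__(self, events: tuple[CnaEvent, ...], chrom_length: int):
        self.chrom_length = chrom_length
        self.intervals: dict[str, list[tuple[int, int, int]]] = {}
        mid = chrom_length // 2
        for ev in events:
            if ev.start is not None:
                s, e = ev.start, ev.end
            elif ev.arm == "p":
                s, e = 0, mid
            elif ev.arm == "q":
                s, e = mid, chrom_length
            else:
                s, e = 0, chrom_length
            self.intervals.setdefault(ev.chrom, []).append((s, e, ev.copy_number))

    def cn_at(self, chrom: str, pos0: int) -> int:
        for s, e, cn in self.intervals.get(chrom, ()):
            if s <= pos0 < e:
                return cn
        return 2

    def as_truth(self) -> list[tuple[str, int, int, int]]:
        out = []
        for chrom, ivs in sorted(self.intervals.items()):
            for s, e, cn in ivs:
                out.append((chrom, s, e, cn))
        return out


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full matched cohort with ground truth.

    Deterministic: the same ``config`` (including ``seed``) yields
    byte-identical serialized output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    events = config.cna_events if config.cna_events is not None else default_cna_profiles(config)
    truth = GroundTruth()
    patients = []
    for pid in range(config.n_patients):
        cn_map = _CopyNumberMap(events.get(pid, ()), config.chrom_length)
        truth.copy_number[pid] = cn_map.as_truth()
        truth.sample_purity[(pid, "germline")] = 0.0
        truth.sample_purity[(pid, "primary")] = config.primary_purities[pid]
        truth.sample_purity[(pid, "model")] = config.model_purities[pid]
        probes = _simulate_probes(rng, config, cn_map, pid)
        sites = _simulate_sites(rng, config, cn_map, pid, truth)
        reads: list[ReadRecord] = []
        if config.model_types[pid] == "xenograft":
            reads = _simulate_reads(rng, config, pid, truth)
        patients.append(PatientData(pid, config.model_types[pid], sites, reads, probes))
    return Cohort(config, patients, truth)


def _simulate_probes(rng, config: CohortConfig, cn_map: _CopyNumberMap,
                     pid: int) -> dict[str, list[TargetProbe]]:
    probe_len = 200
    out: dict[str, list[TargetProbe]] = {"primary": [], "model": []}
    spacing = config.chrom_length // config.probes_per_chrom
    # fragments pooled over the probe: ~probe_len/read_length per unit depth
    frag_per_depth = probe_len / config.read_length
    for ci in range(1, config.n_chromosomes + 1):
        chrom = f"chr{ci}"
        starts = np.arange(config.probes_per_chrom) * spacing + spacing // 4
        gcs = np.clip(rng.normal(0.47, 0.10, size=config.probes_per_chrom), 0.25, 0.78)
        bias_n = gc_coverage_factor(gcs, config.gc_bias_strength)
        bias_t = gc_coverage_factor(
            gcs, config.gc_bias_strength * config.gc_bias_tumor_factor,
            peak=config.gc_bias_tumor_peak)
        frag_mean = config.mean_depth * frag_per_depth
        normal_cov = _nb_draw(rng, frag_mean * bias_n, config.probe_nb_size)
        for sample in ("primary", "model"):
            p = config.primary_purities[pid] if sample == "primary" \
                else config.model_purities[pid]
            cns = np.array([cn_map.cn_at(chrom, int(s)) for s in starts])
            tumor_mean = frag_mean * bias_t * (cns * p + 2.0 * (1.0 - p)) / 2.0
            tumor_cov = _nb_draw(rng, tumor_mean, config.probe_nb_size)
            for j in range(config.probes_per_chrom):
                out[sample].append(TargetProbe(
                    chrom=chrom, start=int(starts[j]), end=int(starts[j]) + probe_len,
                    gc=float(gcs[j]), normal_cov=float(normal_cov[j]),
                    tumor_cov=float(tumor_cov[j])))
    return out


def _draw_snv_alleles(rng) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    # leave transition/transversion choice to the caller
    return ref, ""


def _alt_for(rng, ref: str, ts_probability: float) -> str:
    if rng.random() < ts_probability:
        return _TRANSITION[ref]
    tv = [b for b in _BASES if b != ref and b != _TRANSITION[ref]]
    return tv[rng.integers(2)]


def _site_positions(rng, config: CohortConfig, n: int) -> list[tuple[str, int]]:
    chroms = rng.integers(1, config.n_chromosomes + 1, size=n)
    pos = rng.integers(1, config.chrom_length, size=n)
    return [(f"chr{c}", int(p)) for c, p in zip(chroms, pos)]


def _sample_counts(rng, config, depth_mean, f) -> AlleleCount:
    depth = int(_nb_draw(rng, depth_mean, config.nb_dispersion))
    alt = int(rng.binomial(depth, min(max(f, 0.0), 1.0))) if depth > 0 else 0
    return AlleleCount(ref_count=depth - alt, alt_count=alt)


def _simulate_sites(rng, config: CohortConfig, cn_map: _CopyNumberMap,
                    pid: int, truth: GroundTruth) -> list[SiteObservation]:
    mu_true, mu_art = config.quality_means
    p_primary = config.primary_purities[pid]
    p_model = config.model_purities[pid]
    mouse_frac = config.mouse_read_fractions[pid] \
        if config.model_types[pid] == "xenograft" else 0.0
    sites: list[SiteObservation] = []

    def depth_mean_at():
        gc = float(np.clip(rng.normal(0.47, 0.10), 0.25, 0.78))
        return config.mean_depth * float(gc_coverage_factor(gc, config.gc_bias_strength))

    consequences = list(_CONSEQUENCE_PROBS)
    cons_p = np.array(list(_CONSEQUENCE_PROBS.values()))
    cons_p = cons_p / cons_p.sum()

    # --- germline sites (true het/hom + artifact leaks) ---
    n_art = int(round(config.artifact_fraction * config.n_germline_sites))
    n_true = config.n_germline_sites - n_art
    for chrom, pos in _site_positions(rng, config, n_true):
        het = rng.random() < 2.0 / 3.0
        ref = _BASES[rng.integers(4)]
        alt = _alt_for(rng, ref, config.ts_probability)
        cn = cn_map.cn_at(chrom, pos - 1)
        dm = depth_mean_at()
        counts = {"germline": _sample_counts(rng, config, dm, 0.5 if het else 1.0)}
        for sample, purity in (("primary", p_primary), ("model", p_model)):
            if het:
                # one of the two alleles is gained/lost when CN != 2
                if cn == 2:
                    cn_alt: float = 1.0
                elif cn < 2:
                    cn_alt = float(rng.integers(0, 2))  # lost allele at random
                else:
                    cn_alt = 1.0 + float(rng.integers(0, 2))  # gained allele at random
                f = (cn_alt * purity + (1.0 - purity)) / (cn * purity + 2.0 * (1.0 - purity)) \
                    if (cn * purity + 2.0 * (1.0 - purity)) > 0 else 0.0
            else:
                f = 1.0
            counts[sample] = _sample_counts(rng, config, dm, f)
        known = rng.random() < config.known_germline_fraction
        sites.append(SiteObservation(
            chrom=chrom, pos=pos, ref=ref, alt=alt, variant_type="snv",
            counts=counts,
            mean_alt_quality=float(rng.normal(mu_true, config.quality_sd)),
            consequence=consequences[rng.choice(len(consequences), p=cons_p)],
            known=known, gene=_gene_at(chrom, pos)))
        key = (pid, chrom, pos)
        truth.site_status[key] = "germline_het" if het else "germline_hom"
        truth.site_ccf[key] = float("nan")

    # --- artifact sites: low-quality noise in every sample ---
    for chrom, pos in _site_positions(rng, config, n_art):
        ref = _BASES[rng.integers(4)]
        alt = _alt_for(rng, ref, 0.5)  # artifacts carry no Ts enrichment
        dm = depth_mean_at()
        counts = {s: _sample_counts(rng, config, dm, 0.08)
                  for s in ("germline", "primary", "model")}
        sites.append(SiteObservation(
            chrom=chrom, pos=pos, ref=ref, alt=alt, variant_type="snv",
            counts=counts,
            mean_alt_quality=float(rng.normal(mu_art, config.quality_sd)),
            consequence=consequences[rng.choice(len(consequences), p=cons_p)],
            known=False, gene=_gene_at(chrom, pos)))
        key = (pid, chrom, pos)
        truth.site_status[key] = "artifact"
        truth.site_ccf[key] = float("nan")

    # --- somatic sites ---
    weights = np.asarray(config.subclone_weights)
    for chrom, pos in _site_positions(rng, config, config.n_somatic_sites):
        ccf = float(config.subclone_fractions[rng.choice(len(weights), p=weights)])
        cn = cn_map.cn_at(chrom, pos - 1)
        is_indel = rng.random() < config.indel_fraction
        if is_indel:
            ref = "".join(_BASES[i] for i in rng.integers(0, 4, size=3))
            alt = ref[0]
            vtype = "indel"
        else:
            ref = _BASES[rng.integers(4)]
            alt = _alt_for(rng, ref, config.ts_probability)
            vtype = "snv"
        dm = depth_mean_at()
        counts = {"germline": _sample_counts(rng, config, dm, config.base_error_rate)}
        for sample, purity in (("primary", p_primary), ("model", p_model)):
            f = expected_alt_fraction(1, ccf, purity, cn)
            counts[sample] = _sample_counts(rng, config, dm, f)
        sites.append(SiteObservation(
            chrom=chrom, pos=pos, ref=ref, alt=alt, variant_type=vtype,
            counts=counts,
            mean_alt_quality=float(rng.normal(mu_true, config.quality_sd)),
            consequence=consequences[rng.choice(len(consequences), p=cons_p)],
            known=False, gene=_gene_at(chrom, pos)))
        key = (pid, chrom, pos)
        truth.site_status[key] = "somatic_clonal" if ccf >= 0.99 else "somatic_subclonal"
        truth.site_ccf[key] = ccf

    # --- murine-ortholog artifact sites (xenograft model sample only):
    # mouse-derived reads carry the divergent base, mimicking spurious
    # "somatic" calls that vanish once host reads are removed ---
    n_mouse = int(round(1.5 * config.n_somatic_sites * mouse_frac))
    for chrom, pos in _site_positions(rng, config, n_mouse):
        ref = _BASES[rng.integers(4)]
        alt = _alt_for(rng, ref, 0.5)
        dm = depth_mean_at()
        counts = {"germline": _sample_counts(rng, config, dm, config.base_error_rate),
                  "primary": _sample_counts(rng, config, dm, config.base_error_rate)}
        depth = int(_nb_draw(rng, dm, config.nb_dispersion))
        mouse_alt = int(rng.binomial(depth, mouse_frac)) if depth > 0 else 0
        counts["model"] = AlleleCount(ref_count=depth - mouse_alt, alt_count=mouse_alt)
        sites.append(SiteObservation(
            chrom=chrom, pos=pos, ref=ref, alt=alt, variant_type="snv",
            counts=counts,
            mean_alt_quality=float(rng.normal(mu_true, config.quality_sd)),
            consequence=consequences[rng.choice(len(consequences), p=cons_p)],
            known=False, gene=_gene_at(chrom, pos)))
        key = (pid, chrom, pos)
        truth.site_status[key] = "mouse_artifact"
        truth.site_ccf[key] = float("nan")
        truth.mouse_alt_support[(pid, chrom, pos, "model")] = mouse_alt

    sites.sort(key=lambda s: (int(s.chrom[3:]), s.pos))
    return sites


def _gene_at(chrom: str, pos: int) -> str:
    """Deterministic toy gene symbol from the locus (100 kb gene buckets)."""
    return f"GENE{chrom[3:]}_{pos // 100_000:03d}"


def _simulate_reads(rng, config: CohortConfig, pid: int,
                    truth: GroundTruth) -> list[ReadRecord]:
    L = config.read_length
    mouse_frac = config.mouse_read_fractions[pid]
    species = rng.random(config.n_reads) < mouse_frac  # True = mouse
    reads = []
    for i in range(config.n_reads):
        rid = f"P{pid}_R{i:07d}"
        if species[i]:
            h_map = rng.random() < 0.85
            m_map = rng.random() < 0.98
            h_mm = int(rng.poisson(4.0))
            m_mm = int(rng.poisson(0.5))
            h_pp = rng.random() < 0.30
            m_pp = rng.random() < 0.95
            truth.read_species[(pid, rid)] = "mouse"
        else:
            # graft reads always map to their own genome (fully unmapped
            # fragments never reach a pileup); a quarter cross-map into
            # orthologous mouse loci but always carry extra cross-species
            # substitutions, so their match score never beats the native one
            h_map = True
            m_map = rng.random() < 0.25
            h_mm = int(rng.poisson(0.5))
            m_mm = h_mm + 1 + int(rng.poisson(3.5))
            h_pp = rng.random() < 0.95
            m_pp = False
            truth.read_species[(pid, rid)] = "human"
        if not h_map and not m_map:
            m_map = True  # host read rescued only by its own genome
        h_mm = min(h_mm, L)
        m_mm = min(m_mm, L)
        reads.append(ReadRecord(
            read_id=rid,
            human_mapped=h_map, human_proper_pair=h_pp if h_map else False,
            human_matches=L - h_mm if h_map else 0,
            human_mismatches=h_mm if h_map else 0,
            mouse_mapped=m_map, mouse_proper_pair=m_pp if m_map else False,
            mouse_matches=L - m_mm if m_map else 0,
            mouse_mismatches=m_mm if m_map else 0))
    return reads


def thin_mouse_support(sites: list[SiteObservation], pid: int, truth: GroundTruth,
                       mouse_retention: float, seed: int) -> list[SiteObservation]:
    """Stand-in for re-pileup after read filtering: at each xenograft-sample
    site, murine-attributed alt reads survive independently with probability
    ``mouse_retention`` (the read filter's measured per-species retention).
    Returns new site objects; inputs are untouched.
    """
    rng = np.random.default_rng(seed)
    out = []
    for s in sites:
        key = (pid, s.chrom, s.pos, "model")
        support = truth.mouse_alt_support.get(key, 0)
        if support == 0:
            out.append(s)
            continue
        kept = int(rng.binomial(support, min(max(mouse_retention, 0.0), 1.0)))
        removed = support - kept
        old = s.counts["model"]
        new_counts = dict(s.counts)
        new_counts["model"] = AlleleCount(old.ref_count, max(old.alt_count - removed, 0))
        out.append(dataclasses.replace(s, counts=new_counts))
    return out
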