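"""Core domain records shared across the pipeline.

Conventions: genomic positions on variant sites are 1-based; interval records
(probes, segments, BED/cytoband files) are 0-based half-open.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

CONSEQUENCE_CLASSES = (
    "missense",
    "nonsense",
    "frameshift",
    "inframe_deletion",
    "splice",
    "synonymous",
    "noncoding",
)

NONSYNONYMOUS_CLASSES = (
    "missense",
    "nonsense",
    "frameshift",
    "inframe_deletion",
    "splice",
)


class ValidationError(ValueError):
    """Raised when an input record or parameter violates a contract."""


class InsufficientDataError(ValueError):
    """Raised when an operation is given too few observations to be meaningful."""


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


@dataclass(frozen=True)
class AlleleCount:
    """Reference / alternate read support for one sample at one site."""

    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValidationError(
                f"allele counts must be non-negative, got {self.ref_count}:{self.alt_count}"
            )

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def alt_fraction(self) -> float:
        """Mutant allele frequency: alt / (ref + alt); 0.0 at zero depth."""
        d = self.depth
        return self.alt_count / d if d > 0 else 0.0


@dataclass
class SiteObservation:
    """One candidate variant position with per-sample allele counts.

    ``counts`` maps sample role (e.g. ``"germline"``, ``"primary"``,
    ``"model"``) to :class:`AlleleCount`. ``known`` flags presence in a
    variant database (membership is an input, never looked up here).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_type: str = "snv"  # "snv" | "indel"
    counts: dict[str, AlleleCount] = field(default_factory=dict)
    mean_alt_quality: float = float("nan")
    consequence: str = "noncoding"
    known: bool = False
    gene: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.variant_type not in ("snv", "indel"):
            raise ValidationError(f"unknown variant_type {self.variant_type!r}")
        if self.consequence not in CONSEQUENCE_CLASSES:
            raise ValidationError(f"unknown consequence class {self.consequence!r}")


@dataclass
class VariantCall:
    """Status assigned to a site by the tumor–normal caller."""

    site: SiteObservation
    status: str  # germline | somatic | loh | reference
    somatic_p: float = float("nan")
    filters: dict[str, bool] = field(default_factory=dict)


@dataclass
class ReadRecord:
    """One fragment's alignment summary against the graft (human) and host
    (mouse) genomes. Unmapped genome slots carry zeroed match counts."""

    read_id: str
    human_mapped: bool
    human_proper_pair: bool
    human_matches: int
    human_mismatches: int
    mouse_mapped: bool
    mouse_proper_pair: bool
    mouse_matches: int
    mouse_mismatches: int

    def __post_init__(self) -> None:
        for v in (self.human_matches, self.human_mismatches,
                  self.mouse_matches, self.mouse_mismatches):
            if v < 0:
                raise ValidationError(f"match counts must be >= 0 (read {self.read_id})")


@dataclass(frozen=True)
class SpeciesCall:
    read_id: str
    call: str  # human | mouse | ambiguous
    reason: str  # cascade stage that decided


@dataclass
class TargetProbe:
    """One exome capture interval with GC fraction and mean coverages."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    gc: float
    normal_cov: float
    tumor_cov: float
    logr: float = float("nan")
    nc: bool = False  # not callable (insufficient normal coverage)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"probe end must exceed start ({self.chrom}:{self.start}-{self.end})")
        if not 0.0 <= self.gc <= 1.0:
            raise ValidationError(f"gc must be in [0,1], got {self.gc}")
        if self.normal_cov < 0 or self.tumor_cov < 0:
            raise ValidationError("coverages must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CopySegment:
    """Contiguous run of probes with a shared copy-number state."""

    chrom: str
    start: int
    end: int
    mean_logr: float
    n_probes: int
    call: str = "neutral"  # amp | del | neutral | nc
    confidence: str = "standard"  # hc | standard
    loh: bool = False


@dataclass(frozen=True)
class ArmCall:
    chrom: str
    arm: str  # p | q
    call: str  # amp | del | neutral
    fraction_bp_amp: float
    fraction_bp_del: float


@dataclass
class ComparisonRecord:
    """One somatic site's primary-vs-model contrast."""

    site: SiteObservation
    primary: AlleleCount
    model: AlleleCount
    p_two_sided: float = float("nan")
    q_class: Optional[str] = None  # shared_constant | shared_changing | primary_only | model_only

    @property
    def primary_maf(self) -> float:
        return self.primary.alt_fraction

    @property
    def model_maf(self) -> float:
        return self.model.alt_fraction


@dataclass(frozen=True)
class FdrResult:
    """Permutation-estimated FDR threshold on the observed p-value grid."""

    p_threshold: float
    n_permutations: int
    estimated_fdr_at_threshold: float
    seed: int


@dataclass(frozen=True)
class MixtureFit:
    """Selected Gaussian mixture over mean alt-allele base qualities."""

    n_components: int
    means: tuple[float, ...]
    variances: tuple[float, ...]
    weights: tuple[float, ...]
    assignments: tuple[int, ...]  # per-input component index (ascending mean order)
    model_score: float  # BIC of the selected model (lower is better)
    discard_component: Optional[int] = None  # index flagged for removal (low mode)
    loglik_trace: tuple[float, ...] = ()
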