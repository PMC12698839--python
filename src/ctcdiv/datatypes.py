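"""Core record types shared across the pipeline.

A patient enters the analysis as a :class:`PatientProfile`: the somatic
variants called in their CTC (circulating tumor cell) pool, the copy-number
segmentation of the autosomes, the fraction of mutated microsatellites, and
the clinical covariates with the overall-survival outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError

SILENT = "silent"
NONSILENT = "nonsilent"

AUTOSOMES = tuple(str(c) for c in range(1, 23))


@dataclass(frozen=True)
class VariantCall:
    """One somatic SNV or indel with its supporting read counts.

    ``vaf`` (variant allele frequency) is ``alt_reads / total_reads``; the
    variant class is an SNV iff both alleles have length one, otherwise an
    indel.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    total_reads: int
    alt_reads: int
    gene: str = ""
    consequence: str = SILENT

    def __post_init__(self) -> None:
        if not (0 <= self.alt_reads <= self.total_reads):
            raise ValueError(
                f"alt_reads={self.alt_reads} outside [0, total_reads={self.total_reads}]"
            )
        if self.consequence not in (SILENT, NONSILENT):
            raise ValueError(f"unknown consequence class {self.consequence!r}")

    @property
    def vaf(self) -> float:
        if self.total_reads == 0:
            return 0.0
        return self.alt_reads / self.total_reads

    @property
    def variant_class(self) -> str:
        return "snv" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def is_snv(self) -> bool:
        return self.variant_class == "snv"


@dataclass(frozen=True)
class CNASegment:
    """A copy-number segment on an autosome, 1-based inclusive coordinates.

    ``event`` is one of ``neutral``, ``gain``, ``loss``, ``loh``; the last
    three count as aberrant.
    """

    chrom: str
    start: int
    end: int
    event: str

    VALID_EVENTS = ("neutral", "gain", "loss", "loh")

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.event not in self.VALID_EVENTS:
            raise ValueError(f"unknown segment event {self.event!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_aberrant(self) -> bool:
        return self.event != "neutral"


@dataclass
class PatientProfile:
    """Everything the pipeline knows about one patient."""

    patient_id: str
    variants: list[VariantCall] = field(default_factory=list)
    segments: list[CNASegment] = field(default_factory=list)
    msi_fraction: float = 0.0
    age_years: float = 0.0
    sex: str = "female"
    lines_of_treatment: int = 0
    os_months: float = 0.0
    event: int = 0
    capture_size_mb: float = 1.0
    # ground truth carried by the synthetic generator, absent for real data
    n_clones: int | None = None
    high_diversity: bool | None = None

    def __post_init__(self) -> None:
        if self.os_months < 0:
            raise ValueError("os_months must be >= 0")
        if not 0.0 <= self.msi_fraction <= 1.0:
            raise ValueError("msi_fraction must be in [0, 1]")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")
        if self.sex not in ("female", "male"):
            raise ValueError(f"unknown sex {self.sex!r}")


@dataclass(frozen=True)
class FilterPolicy:
    """Post-calling genotype filter.

    A call is kept iff total depth >= ``min_total_reads`` AND alternate
    depth >= ``min_alt_reads`` AND VAF strictly > ``min_vaf_exclusive``.
    Boundary semantics: total=10 passes, alt=2 passes, vaf=0.075 fails.
    """

    min_total_reads: int = 10
    min_alt_reads: int = 2
    min_vaf_exclusive: float = 0.075

    def __post_init__(self) -> None:
        if self.min_total_reads < 0 or self.min_alt_reads < 0:
            raise ConfigurationError("read-count thresholds must be non-negative")
        if not 0.0 <= self.min_vaf_exclusive < 1.0:
            raise ConfigurationError("min_vaf_exclusive must be in [0, 1)")

    def keeps(self, v: VariantCall) -> bool:
        return (
            v.total_reads >= self.min_total_reads
            and v.alt_reads >= self.min_alt_reads
            and v.vaf > self.min_vaf_exclusive
        )


@dataclass(frozen=True)
class MathPolicy:
    """Depth policy for the MATH score.

    By default only variants with >= 25 total reads and >= 5 alternate reads
    enter the VAF distribution; panel-restricted scoring switches the depth
    filter off. ``mad_scale`` is the consistency constant applied to the raw
    median absolute deviation (1.4826 makes the MAD a consistent estimator of
    the standard deviation under normality, matching the original MATH
    definition; 1.0 gives the raw MAD).
    """

    min_total_reads: int = 25
    min_alt_reads: int = 5
    mad_scale: float = 1.4826
    apply_depth_filter: bool = True
    min_variants: int = 3

    def __post_init__(self) -> None:
        if self.mad_scale <= 0:
            raise ConfigurationError("mad_scale must be > 0")
        if self.min_variants < 1:
            raise ConfigurationError("min_variants must be >= 1")

    def qualifies(self, v: VariantCall) -> bool:
        if not self.apply_depth_filter:
            return True
        return v.total_reads >= self.min_total_reads and v.alt_reads >= self.min_alt_reads


def filter_variants(
    variants: list[VariantCall], policy: FilterPolicy
) -> tuple[list[VariantCall], int]:
    """Apply the genotype filter; returns (kept, number dropped)."""
    kept = [v for v in variants if policy.keeps(v)]
    return kept, len(variants) - len(kept)
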