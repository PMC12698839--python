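"""Per-patient genomic diversity metrics for CTC pools.

Implements the metric set used to summarise a patient's circulating-tumor-cell
pool:

* **MB** — mutational burden: filtered somatic SNVs per megabase of captured
  exome (indels excluded).
* **PAG** — proportion of the autosomal genome covered by copy-number gain,
  loss or LOH segments, with the patient's own segmentation as denominator.
* **MATH** — mutant-allele tumor heterogeneity:
  ``100 * MAD(VAF) / median(VAF)`` over the SNV+indel VAF distribution,
  by default restricted to sites with >= 25 total and >= 5 alternate reads.
* **CRC-mut / CRC-CNA** — counts of non-silent driver-gene mutations and of
  aberrant-segment x driver-gene overlap pairs.
* **gene status** — per-patient mutated/unmutated status at driver genes
  recurrently hit across the cohort.
* **MSI** — microsatellite instability: > 30% of microsatellites mutated.

Downstream survival analyses are restricted to microsatellite-stable (MSS)
patients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    NONSILENT,
    CNASegment,
    MathPolicy,
    PatientProfile,
    VariantCall,
)
from .errors import AnalysisError

logger = logging.getLogger(__name__)

MSI_FRACTION_THRESHOLD = 0.30

MSS = "MSS"
MSI = "MSI"

UNMUTATED = "unmutated"
MUTATED = "mutated"


def mutational_burden(variants: list[VariantCall], capture_size_mb: float) -> float:
    """SNVs per megabase of captured exome; indels do not count."""
    if capture_size_mb <= 0:
        raise AnalysisError(f"capture_size_mb must be > 0, got {capture_size_mb}")
    return sum(1 for v in variants if v.is_snv) / capture_size_mb


def proportion_aberrant_genome(segments: list[CNASegment]) -> float | None:
    """Fraction of segmented autosomal genome with gain/loss/LOH.

    The denominator is the total length of the patient's segmentation (the
    callable genome), not a genome-build constant. ``None`` (missing) when
    the patient has no segments — absence of segmentation is not PAG = 0.
    """
    total = sum(s.length for s in segments)
    if total == 0:
        return None
    aberrant = sum(s.length for s in segments if s.is_aberrant)
    return aberrant / total


def math_score(variants: list[VariantCall],
               policy: MathPolicy | None = None) -> float | None:
    """Mutant-allele tumor heterogeneity over SNV and indel VAFs.

    ``100 * mad_scale * median(|VAF - median(VAF)|) / median(VAF)`` after the
    policy's depth filter. Returns ``None`` when fewer than
    ``policy.min_variants`` variants qualify (a MAD needs at least 3 points
    to be non-degenerate).
    """
    if policy is None:
        policy = MathPolicy()
    vafs = np.asarray([v.vaf for v in variants if policy.qualifies(v)], dtype=float)
    if vafs.size < policy.min_variants:
        logger.info("MATH missing: only %d qualifying variants (< %d)",
                    vafs.size, policy.min_variants)
        return None
    med = float(np.median(vafs))
    if med == 0.0:
        raise AnalysisError("median VAF is 0; MATH undefined")
    mad = float(np.median(np.abs(vafs - med)))
    return 100.0 * policy.mad_scale * mad / med


def _norm_gene(g: str) -> str:
    return g.strip().upper()


def crc_driver_mut_count(variants: list[VariantCall],
                         driver_genes: list[str] | tuple[str, ...]) -> int:
    """Non-silent SNVs+indels in driver genes (case-insensitive symbols)."""
    drivers = {_norm_gene(g) for g in driver_genes}
    return sum(1 for v in variants
               if v.consequence == NONSILENT and _norm_gene(v.gene) in drivers)


def crc_driver_cna_count(segments: list[CNASegment],
                         driver_gene_coords: dict[str, tuple[str, int, int]]) -> int:
    """Aberrant-segment x driver-gene overlap pairs.

    A gene overlapped by two aberrant segments contributes 2; overlap is a
    non-empty intersection of 1-based inclusive intervals.
    """
    count = 0
    for chrom, gstart, gend in driver_gene_coords.values():
        for seg in segments:
            if (seg.is_aberrant and seg.chrom == str(chrom)
                    and seg.start <= gend and gstart <= seg.end):
                count += 1
    return count


def recurrent_gene_status(
    cohort: list[PatientProfile],
    driver_genes: list[str] | tuple[str, ...],
    min_patients: int = 4,
) -> dict[str, dict[str, str]]:
    """Mutation status at recurrently mutated driver genes.

    Selects driver genes carrying a non-silent SNV/indel in at least
    ``min_patients`` patients and returns, per selected gene, each patient's
    mutated/unmutated status.
    """
    if min_patients < 1:
        raise AnalysisError("min_patients must be >= 1")
    drivers = {_norm_gene(g): g for g in driver_genes}
    mutated: dict[str, set[str]] = {g: set() for g in drivers}
    for p in cohort:
        for v in p.variants:
            g = _norm_gene(v.gene)
            if v.consequence == NONSILENT and g in drivers:
                mutated[g].add(p.patient_id)
    status: dict[str, dict[str, str]] = {}
    for g, patients in mutated.items():
        if len(patients) >= min_patients:
            status[drivers[g]] = {
                p.patient_id: (MUTATED if p.patient_id in patients else UNMUTATED)
                for p in cohort
            }
    return status


def msi_classify(msi_fraction: float) -> str:
    """MSI iff strictly more than 30% of microsatellites are mutated."""
    if not 0.0 <= msi_fraction <= 1.0:
        raise AnalysisError(f"msi_fraction must be in [0, 1], got {msi_fraction}")
    return MSI if msi_fraction > MSI_FRACTION_THRESHOLD else MSS


def restrict_to_mss(cohort: list[PatientProfile]) -> list[PatientProfile]:
    """Drop microsatellite-instable patients before survival analysis."""
    kept = [p for p in cohort if msi_classify(p.msi_fraction) == MSS]
    excluded = [p.patient_id for p in cohort
                if msi_classify(p.msi_fraction) == MSI]
    if excluded:
        logger.info("excluded %d MSI patients: %s", len(excluded), excluded)
    if not kept:
        logger.warning("all patients are MSI; nothing left to analyse")
    return kept


@dataclass
class DiversityMetrics:
    """The per-patient metric vector."""

    patient_id: str
    mb: float
    pag: float | None
    math: float | None
    crc_mut: int
    crc_cna: int
    msi_fraction: float
    msi_status: str
    gene_status: dict[str, str]


def compute_cohort_metrics(
    cohort: list[PatientProfile],
    driver_genes: list[str] | tuple[str, ...],
    driver_coords: dict[str, tuple[str, int, int]],
    math_policy: MathPolicy | None = None,
    min_patients: int = 4,
) -> pd.DataFrame:
    """Metric table: one row per patient, one column per metric.

    Gene-status columns are named ``gene_<SYMBOL>`` with values
    mutated/unmutated; missing MATH/PAG are NaN.
    """
    gene_status = recurrent_gene_status(cohort, driver_genes, min_patients)
    rows = []
    for p in cohort:
        pag = proportion_aberrant_genome(p.segments)
        row = {
            "patient_id": p.patient_id,
            "mb": mutational_burden(p.variants, p.capture_size_mb),
            "pag": np.nan if pag is None else pag,
            "math": np.nan if (m := math_score(p.variants, math_policy)) is None else m,
            "crc_mut": crc_driver_mut_count(p.variants, driver_genes),
            "crc_cna": crc_driver_cna_count(p.segments, driver_coords),
            "msi_fraction": p.msi_fraction,
            "msi_status": msi_classify(p.msi_fraction),
            "age_years": p.age_years,
            "sex": p.sex,
            "lines_of_treatment": p.lines_of_treatment,
            "os_months": p.os_months,
            "event": p.event,
        }
        for gene, per_patient in gene_status.items():
            row[f"gene_{gene}"] = per_patient[p.patient_id]
        rows.append(row)
    return pd.DataFrame(rows)
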