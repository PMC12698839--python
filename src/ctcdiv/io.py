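"""Readers for the pipeline's standard inputs.

The pipeline starts from the outputs of somatic variant calling: per-patient
VCFs (with DP/AD depths and GENE/CSQCLASS annotations), Sequenza-like
copy-number segment tables, a microsatellite-instability fraction per
patient, a clinical table, a driver-gene list with coordinates, and a
capture BED giving the exome footprint. Reading applies the post-calling
genotype filter: calls with < 10 total reads, < 2 alternate reads, or a
variant allele frequency <= 0.075 are treated as missing and dropped.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from cyvcf2 import VCF

from .datatypes import (
    AUTOSOMES,
    NONSILENT,
    SILENT,
    CNASegment,
    FilterPolicy,
    PatientProfile,
    VariantCall,
)
from .errors import InputError

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = ["patient_id", "age_years", "sex", "lines_of_treatment",
                    "os_months", "event"]


def read_patient_vcf(path: str | Path, policy: FilterPolicy | None = None
                     ) -> tuple[list[VariantCall], int]:
    """Read one patient's somatic VCF and apply the genotype filter.

    Returns ``(kept, dropped)`` where dropped counts records failing the
    filter or lacking usable DP/AD. Multi-allelic records are split into one
    call per alternate allele with per-allele AD.
    """
    if policy is None:
        policy = FilterPolicy()
    kept: list[VariantCall] = []
    dropped = 0
    missing_csq = 0
    for rec in VCF(str(path)):
        gene = rec.INFO.get("GENE") or ""
        csq = rec.INFO.get("CSQCLASS")
        if csq not in (SILENT, NONSILENT):
            # unannotated consequence: conservative for driver metrics
            missing_csq += 1
            csq = SILENT
        dp_arr = rec.format("DP")
        ad_arr = rec.format("AD")
        if dp_arr is None or ad_arr is None:
            dropped += len(rec.ALT)
            continue
        total = int(dp_arr[0][0])
        if total < 0:  # cyvcf2 encodes missing as a large negative sentinel
            dropped += len(rec.ALT)
            continue
        for allele_idx, alt in enumerate(rec.ALT):
            alt_reads = int(ad_arr[0][allele_idx + 1])
            if alt_reads < 0 or alt_reads > total:
                dropped += 1
                continue
            call = VariantCall(
                chrom=str(rec.CHROM), pos=rec.POS, ref=rec.REF, alt=alt,
                total_reads=total, alt_reads=alt_reads,
                gene=gene.strip(), consequence=csq,
            )
            if policy.keeps(call):
                kept.append(call)
            else:
                dropped += 1
    if missing_csq:
        logger.warning("%s: %d records lacked CSQCLASS; treated as silent",
                       path, missing_csq)
    return kept, dropped


def read_segments(path: str | Path) -> list[CNASegment]:
    """Read a copy-number segment table; autosomes only, overlaps rejected."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["chrom", "start", "end", "event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing segment columns {missing}")
    non_auto = df[~df["chrom"].isin(AUTOSOMES)]
    if len(non_auto):
        logger.info("%s: excluded %d non-autosomal segments", path, len(non_auto))
    df = df[df["chrom"].isin(AUTOSOMES)]
    segments = []
    for row in df.itertuples(index=False):
        try:
            segments.append(CNASegment(chrom=str(row.chrom), start=int(row.start),
                                       end=int(row.end), event=str(row.event)))
        except ValueError as exc:
            raise InputError(f"{path}: invalid segment {tuple(row)}: {exc}") from exc
    # overlap would make the aberrant-genome fraction ambiguous
    by_chrom: dict[str, list[CNASegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs[:-1], segs[1:]):
            if b.start <= a.end:
                raise InputError(
                    f"{path}: overlapping segments on chromosome {chrom}: "
                    f"({a.start}-{a.end}) and ({b.start}-{b.end})")
    return segments


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the clinical table; exact header, typed columns, event in {0,1}."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "sex": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing clinical columns {missing}")
    df = df[CLINICAL_COLUMNS].copy()
    for col in ("age_years", "os_months"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            rows = df.index[bad].tolist()
            raise InputError(f"{path}: non-numeric {col} in rows {rows}") from exc
    df["lines_of_treatment"] = pd.to_numeric(df["lines_of_treatment"]).astype(int)
    df["sex"] = df["sex"].str.strip().str.lower()
    bad_sex = ~df["sex"].isin(["female", "male"])
    if bad_sex.any():
        raise InputError(f"{path}: invalid sex values {df.loc[bad_sex, 'sex'].tolist()}")
    df["event"] = pd.to_numeric(df["event"]).astype(int)
    bad_ev = ~df["event"].isin([0, 1])
    if bad_ev.any():
        raise InputError(f"{path}: event must be 0 or 1; offending rows "
                         f"{df.index[bad_ev].tolist()}")
    if (df["os_months"] < 0).any():
        raise InputError(f"{path}: negative os_months")
    return df


def read_msi(path: str | Path) -> dict[str, float]:
    """Per-patient fraction of mutated microsatellites."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    for col in ("patient_id", "msi_fraction"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col}")
    fractions = pd.to_numeric(df["msi_fraction"])
    if ((fractions < 0) | (fractions > 1)).any():
        raise InputError(f"{path}: msi_fraction outside [0, 1]")
    return dict(zip(df["patient_id"], fractions.astype(float)))


def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text gene list, one symbol per line, ``#`` comments allowed."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#")[0].strip()
        if line:
            genes.append(line)
    return genes


def read_gene_coords(path: str | Path) -> dict[str, tuple[str, int, int]]:
    """Gene coordinate table: gene, chrom, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    for col in ("gene", "chrom", "start", "end"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col}")
    return {row.gene: (str(row.chrom), int(row.start), int(row.end))
            for row in df.itertuples(index=False)}


def bed_to_capture_size_mb(path: str | Path) -> float:
    """Total footprint of a 0-based half-open BED, in megabases."""
    total = 0
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise InputError(f"{path}: malformed BED line {ln}")
        start, end = int(parts[1]), int(parts[2])
        if end < start:
            raise InputError(f"{path}: end < start on BED line {ln}")
        total += end - start
    return total / 1e6


def load_cohort(cohort_dir: str | Path,
                policy: FilterPolicy | None = None) -> list[PatientProfile]:
    """Assemble PatientProfiles from a cohort directory.

    Expects the layout written by :func:`ctcdiv.simulate.write_cohort`:
    ``clinical.tsv``, ``msi.tsv``, ``capture.bed``, ``vcf/<id>.vcf`` and
    ``segments/<id>.segments.tsv``.
    """
    root = Path(cohort_dir)
    clinical = read_clinical(root / "clinical.tsv")
    msi = read_msi(root / "msi.tsv")
    capture_mb = bed_to_capture_size_mb(root / "capture.bed")
    cohort = []
    for row in clinical.itertuples(index=False):
        pid = row.patient_id
        vcf_path = root / "vcf" / f"{pid}.vcf"
        seg_path = root / "segments" / f"{pid}.segments.tsv"
        if not vcf_path.exists():
            raise InputError(f"missing VCF for patient {pid}: {vcf_path}")
        variants, dropped = read_patient_vcf(vcf_path, policy)
        logger.info("%s: kept %d variants, dropped %d", pid, len(variants), dropped)
        segments = read_segments(seg_path) if seg_path.exists() else []
        if pid not in msi:
            raise InputError(f"no MSI fraction for patient {pid}")
        cohort.append(PatientProfile(
            patient_id=pid, variants=variants, segments=segments,
            msi_fraction=msi[pid], age_years=float(row.age_years),
            sex=row.sex, lines_of_treatment=int(row.lines_of_treatment),
            os_months=float(row.os_months), event=int(row.event),
            capture_size_mb=capture_mb,
        ))
    return cohort
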