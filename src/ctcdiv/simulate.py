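"""Synthetic CTC-pool cohort generator.

Generates cohorts with the statistical structure the downstream analysis
assumes: each patient's somatic variants are drawn from a mixture of a
clonal cluster and ``K-1`` subclonal clusters, read depths are
overdispersed (negative binomial totals, binomial alternate counts),
copy-number segments tile the 22 autosomes with a patient-specific aberrant
fraction, one patient in ~29 is microsatellite instable, and survival times
follow an exponential proportional-hazards model with planted effects of
the diversity stratum, driver-gene mutation status and age.

The "high diversity" stratum is defined *generatively* — a patient is high
diversity iff their number of clones is at least
``high_diversity_min_clones`` — so parameter-recovery experiments do not
depend on any estimated MATH cutoff.

Randomness uses one root seed split into counter-based per-patient
substreams (``default_rng([seed, patient_index])``), so each patient is
reproducible independently of cohort ordering.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .datatypes import AUTOSOMES, NONSILENT, SILENT, CNASegment, PatientProfile, VariantCall
from .errors import ConfigurationError

# Autosome lengths in bp (GRCh38, rounded to 0.1 Mb); used to tile segments
# and to place variants. The PAG denominator never uses these directly — it
# is the total length of the patient's own segmentation.
AUTOSOME_LENGTHS = {
    "1": 248_900_000, "2": 242_200_000, "3": 198_300_000, "4": 190_200_000,
    "5": 181_500_000, "6": 170_800_000, "7": 159_300_000, "8": 145_100_000,
    "9": 138_400_000, "10": 133_800_000, "11": 135_100_000, "12": 133_300_000,
    "13": 114_400_000, "14": 107_000_000, "15": 101_900_000, "16": 90_300_000,
    "17": 83_300_000, "18": 80_400_000, "19": 58_600_000, "20": 64_400_000,
    "21": 46_700_000, "22": 50_800_000,
}

# Recurrently mutated colorectal-cancer driver genes with per-patient
# non-silent mutation probabilities chosen to emulate a typical mCRC cohort
# (APC/TP53/KRAS near-ubiquitous, the rest recurrent but sparser).
DEFAULT_GENE_MUT_PROB = {
    "APC": 0.70, "TP53": 0.65, "KRAS": 0.45, "FAT4": 0.35, "BCL9L": 0.30,
    "PIK3CA": 0.25, "SMAD4": 0.20, "FBXW7": 0.20, "TCF7L2": 0.18,
    "SOX9": 0.15, "BRAF": 0.12, "AMER1": 0.10, "ARID1A": 0.10,
    "ATM": 0.08, "KMT2C": 0.08, "PTEN": 0.06, "NRAS": 0.05,
    "CTNNB1": 0.05, "RNF43": 0.05, "GRIN2A": 0.04,
}

DEFAULT_DRIVER_GENES = tuple(DEFAULT_GENE_MUT_PROB)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a 29-patient metastatic-colorectal-cancer cohort:
    ages ~N(66.28, 16.33) truncated to [18, 95], 34.5% female, roughly one
    MSI patient expected, and planted hazards of 3.5 for the high-diversity
    stratum, 6.0 for BCL9L mutation and 1.07 per year of age.
    """

    n_patients: int = 29
    seed: int = 0
    # clone structure
    n_clones_range: tuple[int, int] = (1, 4)
    clonal_vaf_center: float = 0.40
    subclonal_vaf_range: tuple[float, float] = (0.08, 0.30)
    clonal_fraction: float = 0.5  # expected fraction of variants in the clonal cluster
    high_diversity_min_clones: int = 3
    # depth model
    depth_mean: float = 80.0
    depth_dispersion: float = 4.0  # negative-binomial size parameter
    # mutation landscape
    n_variants_range: tuple[int, int] = (350, 1250)
    fraction_indel: float = 0.65
    fraction_nonsilent: float = 0.5
    driver_genes: tuple[str, ...] = DEFAULT_DRIVER_GENES
    gene_mut_prob: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENE_MUT_PROB)
    )
    # long-tailed passenger gene-frequency landscape: two tiers of
    # frequently hit genes over a large quiet background, emulating the
    # skewed per-gene mutation counts real cohorts show
    n_hot_genes: tuple[int, int] = (25, 40)
    hot_gene_prob: tuple[float, float] = (0.021, 0.016)
    n_background_genes: int = 18000
    # copy number
    n_segments_range: tuple[int, int] = (120, 300)
    aberrant_segment_prob: float = 0.12
    aberrant_prob_concentration: float = 5.0  # Beta concentration for patient-level rate
    # microsatellite instability
    msi_prob: float = 1.0 / 29.0
    # capture
    capture_size_mb: float = 120.0
    # clinical covariates
    age_mean: float = 66.28
    age_sd: float = 16.33
    age_bounds: tuple[float, float] = (18.0, 95.0)
    prob_female: float = 0.345
    lot_mean: float = 2.0  # Poisson mean for lines of treatment
    # survival model
    baseline_hazard: float = math.log(2) / 30.0  # events/month; median ~30 months
    log_hr_math_high: float = math.log(3.5)
    log_hr_gene: dict[str, float] = field(
        default_factory=lambda: {"BCL9L": math.log(6.0)}
    )
    log_hr_age: float = math.log(1.07)
    censor_rate: float = 0.3
    max_followup_months: float = 100.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        fracs = {
            "clonal_vaf_center": self.clonal_vaf_center,
            "clonal_fraction": self.clonal_fraction,
            "fraction_indel": self.fraction_indel,
            "fraction_nonsilent": self.fraction_nonsilent,
            "aberrant_segment_prob": self.aberrant_segment_prob,
            "msi_prob": self.msi_prob,
            "prob_female": self.prob_female,
            "censor_rate": self.censor_rate,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        for name in ("n_clones_range", "n_variants_range", "n_segments_range",
                     "subclonal_vaf_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} must satisfy min <= max, got {(lo, hi)}")
        for name in ("depth_mean", "depth_dispersion", "capture_size_mb",
                     "baseline_hazard", "max_followup_months"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if self.n_clones_range[0] < 1:
            raise ConfigurationError("n_clones_range minimum must be >= 1")
        lo, hi = self.subclonal_vaf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError("subclonal_vaf_range must lie inside (0, 1)")
        unknown = set(self.gene_mut_prob) - set(self.driver_genes)
        if unknown:
            raise ConfigurationError(
                f"gene_mut_prob names genes outside driver_genes: {sorted(unknown)}"
            )
        unknown_hr = set(self.log_hr_gene) - set(self.driver_genes)
        if unknown_hr:
            raise ConfigurationError(
                f"log_hr_gene names genes outside driver_genes: {sorted(unknown_hr)}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["driver_genes"] = list(self.driver_genes)
        for key in ("n_clones_range", "n_variants_range", "n_segments_range",
                    "subclonal_vaf_range", "age_bounds", "n_hot_genes",
                    "hot_gene_prob"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        for key in ("n_clones_range", "n_variants_range", "n_segments_range",
                    "subclonal_vaf_range", "age_bounds", "n_hot_genes",
                    "hot_gene_prob"):
            if key in d:
                d[key] = tuple(d[key])
        if "driver_genes" in d:
            d["driver_genes"] = tuple(d["driver_genes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def driver_gene_coords(genes: tuple[str, ...] | list[str]) -> dict[str, tuple[str, int, int]]:
    """Deterministic synthetic coordinates for driver genes.

    Genes are laid out round-robin across the 22 autosomes at 5-Mb spacing
    with 150-kb bodies — enough structure for segment-overlap counting
    without any external annotation resource.
    """
    coords: dict[str, tuple[str, int, int]] = {}
    for i, gene in enumerate(genes):
        chrom = AUTOSOMES[i % 22]
        start = 10_000_000 + (i // 22) * 5_000_000 + (i % 22) * 1_000_000
        coords[gene] = (chrom, start, start + 150_000)
    return coords


def patient_rng(seed: int, patient_index: int) -> np.random.Generator:
    """Counter-based substream: reproducible per patient under reordering."""
    return np.random.default_rng([seed, patient_index])


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def _draw_depths(rng: np.random.Generator, n: int, mean: float, dispersion: float
                 ) -> np.ndarray:
    # NB(size=r, p=r/(r+mean)) has the requested mean with variance
    # mean + mean^2/r; clip at 1 read so VAF is defined for every record.
    p = dispersion / (dispersion + mean)
    return np.maximum(rng.negative_binomial(dispersion, p, size=n), 1)


def simulate_patient(config: SimConfig, patient_index: int,
                     rng: np.random.Generator | None = None) -> PatientProfile:
    """Draw one synthetic patient.

    Variants come from ``K`` clones (``K`` uniform over ``n_clones_range``);
    clone 1 sits at ``clonal_vaf_center``, subclones at VAFs uniform over
    ``subclonal_vaf_range``. Each variant draws a negative-binomial total
    depth and a binomial alternate count at its clone's VAF.
    """
    if patient_index >= config.n_patients:
        raise ConfigurationError(
            f"patient_index {patient_index} >= n_patients {config.n_patients}"
        )
    if rng is None:
        rng = patient_rng(config.seed, patient_index)
    pid = f"P{patient_index + 1:03d}"

    # clinical covariates
    age = _truncated_normal(rng, config.age_mean, config.age_sd, *config.age_bounds)
    sex = "female" if rng.random() < config.prob_female else "male"
    lot = int(rng.poisson(config.lot_mean))

    # clone structure
    k_lo, k_hi = config.n_clones_range
    n_clones = int(rng.integers(k_lo, k_hi + 1))
    clone_vafs = np.empty(n_clones)
    clone_vafs[0] = config.clonal_vaf_center
    if n_clones > 1:
        clone_vafs[1:] = rng.uniform(*config.subclonal_vaf_range, size=n_clones - 1)
    high = n_clones >= config.high_diversity_min_clones

    # driver-gene hits: one forced non-silent variant per hit gene
    coords = driver_gene_coords(config.driver_genes)
    hit_genes = [g for g in config.driver_genes
                 if rng.random() < config.gene_mut_prob.get(g, 0.0)]

    n_passenger = int(rng.integers(config.n_variants_range[0],
                                   config.n_variants_range[1] + 1))
    n_total = len(hit_genes) + n_passenger

    # per-variant clone assignment: clonal cluster with prob clonal_fraction,
    # otherwise a uniformly chosen subclone (all clonal when K = 1)
    if n_clones == 1:
        clone_idx = np.zeros(n_total, dtype=int)
    else:
        clonal = rng.random(n_total) < config.clonal_fraction
        clone_idx = np.where(
            clonal, 0, rng.integers(1, n_clones, size=n_total))
    totals = _draw_depths(rng, n_total, config.depth_mean, config.depth_dispersion)
    alts = rng.binomial(totals, clone_vafs[clone_idx])

    # vectorized per-variant draws (alleles, genes, positions, consequences)
    n_pass = n_total - len(hit_genes)
    is_indel = rng.random(n_total) < config.fraction_indel
    ref_idx = rng.integers(4, size=n_total)
    alt_shift = rng.integers(3, size=n_total)
    ins_idx = rng.integers(4, size=(n_total, 2))
    is_insertion = rng.random(n_total) < 0.5
    tier_u = rng.random(n_pass)
    hot_a = rng.integers(config.n_hot_genes[0], size=n_pass)
    hot_b = rng.integers(config.n_hot_genes[1], size=n_pass)
    background = rng.integers(config.n_background_genes, size=n_pass)
    pass_chrom_idx = rng.integers(22, size=n_pass)
    pass_pos_u = rng.random(n_pass)
    pass_nonsilent = rng.random(n_pass) < config.fraction_nonsilent

    bases = "ACGT"
    p_a, p_ab = config.hot_gene_prob[0], sum(config.hot_gene_prob)
    variants: list[VariantCall] = []
    seen_pos: set[tuple[str, int]] = set()
    for i in range(n_total):
        ref = bases[ref_idx[i]]
        if is_indel[i]:
            ins = bases[ins_idx[i, 0]] + bases[ins_idx[i, 1]]
            ref, alt_allele = (ref, ref + ins) if is_insertion[i] else (ref + ins, ref)
        else:
            alt_allele = bases[(ref_idx[i] + 1 + alt_shift[i]) % 4]
        if i < len(hit_genes):
            gene = hit_genes[i]
            chrom, gstart, gend = coords[gene]
            pos = int(rng.integers(gstart, gend + 1))
            csq = NONSILENT
        else:
            j = i - len(hit_genes)
            if tier_u[j] < p_a:
                gene = f"HOTA{hot_a[j]:03d}"
            elif tier_u[j] < p_ab:
                gene = f"HOTB{hot_b[j]:03d}"
            else:
                gene = f"GENE{background[j]:05d}"
            chrom = AUTOSOMES[pass_chrom_idx[j]]
            pos = 1 + int(pass_pos_u[j] * (AUTOSOME_LENGTHS[chrom] - 1))
            csq = NONSILENT if pass_nonsilent[j] else SILENT
        while (chrom, pos) in seen_pos:
            pos += 1
        seen_pos.add((chrom, pos))
        variants.append(VariantCall(
            chrom=chrom, pos=pos, ref=ref, alt=alt_allele,
            total_reads=int(totals[i]), alt_reads=int(alts[i]),
            gene=gene, consequence=csq,
        ))
    variants.sort(key=lambda v: (int(v.chrom), v.pos))

    # copy-number segments tiling the 22 autosomes; patient-level aberrant
    # rate drawn from a Beta around aberrant_segment_prob for inter-patient
    # PAG spread
    if config.aberrant_segment_prob in (0.0, 1.0):
        p_aberrant = config.aberrant_segment_prob
    else:
        c = config.aberrant_prob_concentration
        p_aberrant = float(rng.beta(config.aberrant_segment_prob * c,
                                    (1 - config.aberrant_segment_prob) * c))
    n_segments = int(rng.integers(config.n_segments_range[0],
                                  config.n_segments_range[1] + 1))
    segments = _tile_segments(rng, n_segments, p_aberrant)

    # microsatellite instability fraction
    if rng.random() < config.msi_prob:
        msi_fraction = float(rng.uniform(0.31, 0.85))
    else:
        msi_fraction = float(rng.uniform(0.005, 0.25))

    # survival under the planted proportional-hazards model
    log_hazard = math.log(config.baseline_hazard)
    if high:
        log_hazard += config.log_hr_math_high
    for gene, lhr in config.log_hr_gene.items():
        if gene in hit_genes:
            log_hazard += lhr
    log_hazard += config.log_hr_age * (age - config.age_mean)
    t_event = float(rng.exponential(1.0 / math.exp(log_hazard)))
    if rng.random() < config.censor_rate:
        t_censor = float(rng.uniform(0.0, config.max_followup_months))
    else:
        t_censor = config.max_followup_months
    os_months = min(t_event, t_censor)
    event = int(t_event <= t_censor)

    return PatientProfile(
        patient_id=pid, variants=variants, segments=segments,
        msi_fraction=msi_fraction, age_years=age, sex=sex,
        lines_of_treatment=lot, os_months=os_months, event=event,
        capture_size_mb=config.capture_size_mb,
        n_clones=n_clones, high_diversity=high,
    )


def _tile_segments(rng: np.random.Generator, n_segments: int,
                   p_aberrant: float) -> list[CNASegment]:
    """Partition each autosome into contiguous segments; total count ~= n_segments
    allocated proportionally to chromosome length (at least 1 per autosome)."""
    total_len = sum(AUTOSOME_LENGTHS.values())
    segments: list[CNASegment] = []
    for chrom in AUTOSOMES:
        clen = AUTOSOME_LENGTHS[chrom]
        n_chrom = max(1, round(n_segments * clen / total_len))
        # random interior breakpoints
        if n_chrom > 1:
            breaks = np.sort(rng.integers(2, clen, size=n_chrom - 1))
            breaks = np.unique(breaks)
        else:
            breaks = np.array([], dtype=int)
        bounds = np.concatenate(([1], breaks, [clen + 1]))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if rng.random() < p_aberrant:
                event = ("gain", "loss", "loh")[int(rng.integers(3))]
            else:
                event = "neutral"
            segments.append(CNASegment(chrom=chrom, start=int(lo),
                                       end=int(hi) - 1, event=event))
    return segments


def simulate_cohort(config: SimConfig) -> list[PatientProfile]:
    """Draw the full cohort from per-patient substreams of ``config.seed``."""
    return [simulate_patient(config, i) for i in range(config.n_patients)]


# ---------------------------------------------------------------------------
# writers

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQCLASS,Number=1,Type=String,Description="Consequence class: silent|nonsilent">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
"""


def write_patient_vcf(patient: PatientProfile, path: Path) -> None:
    lines = [_VCF_HEADER]
    for chrom in AUTOSOMES:
        lines.append(f"##contig=<ID={chrom},length={AUTOSOME_LENGTHS[chrom]}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{patient.patient_id}\n")
    for v in patient.variants:
        info = f"GENE={v.gene};CSQCLASS={v.consequence}" if v.gene else \
               f"CSQCLASS={v.consequence}"
        ref_reads = v.total_reads - v.alt_reads
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\t"
            f"GT:DP:AD\t0/1:{v.total_reads}:{ref_reads},{v.alt_reads}\n")
    path.write_text("".join(lines))


def write_segments(patient: PatientProfile, path: Path) -> None:
    lines = ["chrom\tstart\tend\tevent\n"]
    for s in patient.segments:
        lines.append(f"{s.chrom}\t{s.start}\t{s.end}\t{s.event}\n")
    path.write_text("".join(lines))


def write_capture_bed(capture_size_mb: float, path: Path) -> None:
    """One interval per autosome, lengths proportional to chromosome size and
    summing exactly to the requested capture footprint (0-based half-open)."""
    total_bp = int(round(capture_size_mb * 1e6))
    genome = sum(AUTOSOME_LENGTHS.values())
    lines = []
    allocated = 0
    for i, chrom in enumerate(AUTOSOMES):
        if i == len(AUTOSOMES) - 1:
            length = total_bp - allocated
        else:
            length = int(round(total_bp * AUTOSOME_LENGTHS[chrom] / genome))
        allocated += length
        lines.append(f"{chrom}\t1000000\t{1000000 + length}\n")
    path.write_text("".join(lines))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_cohort(cohort: list[PatientProfile], out_dir: str | Path,
                 config: SimConfig | None = None) -> dict:
    """Write the cohort in the pipeline's input formats; returns the manifest.

    Emits per-patient VCFs and segment tables, the clinical and MSI tables,
    the driver-gene list with synthetic coordinates, and the capture BED.
    """
    out = Path(out_dir)
    (out / "vcf").mkdir(parents=True, exist_ok=True)
    (out / "segments").mkdir(parents=True, exist_ok=True)

    clin = ["patient_id\tage_years\tsex\tlines_of_treatment\tos_months\tevent\n"]
    msi = ["patient_id\tmsi_fraction\n"]
    for p in cohort:
        write_patient_vcf(p, out / "vcf" / f"{p.patient_id}.vcf")
        write_segments(p, out / "segments" / f"{p.patient_id}.segments.tsv")
        clin.append(f"{p.patient_id}\t{p.age_years:.4f}\t{p.sex}\t"
                    f"{p.lines_of_treatment}\t{p.os_months:.6f}\t{p.event}\n")
        msi.append(f"{p.patient_id}\t{p.msi_fraction:.6f}\n")
    (out / "clinical.tsv").write_text("".join(clin))
    (out / "msi.tsv").write_text("".join(msi))

    genes = config.driver_genes if config is not None else DEFAULT_DRIVER_GENES
    (out / "drivers.txt").write_text("".join(f"{g}\n" for g in genes))
    coords = driver_gene_coords(genes)
    coord_lines = ["gene\tchrom\tstart\tend\n"]
    for g, (chrom, start, end) in coords.items():
        coord_lines.append(f"{g}\t{chrom}\t{start}\t{end}\n")
    (out / "driver_coords.tsv").write_text("".join(coord_lines))

    capture = (config.capture_size_mb if config is not None
               else (cohort[0].capture_size_mb if cohort else 120.0))
    write_capture_bed(capture, out / "capture.bed")

    files = sorted(str(p.relative_to(out)) for p in out.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "n_patients": len(cohort),
        "files": {f: _sha256(out / f) for f in files},
    }
    if config is not None:
        manifest["config"] = config.to_dict()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
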