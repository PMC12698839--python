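"""End-to-end pipeline: simulate/load -> filter -> metrics -> survival -> panels.

One RunConfig drives the full analysis; every stage writes TSV outputs under
the run directory and the run manifest records the config snapshot, seed,
and a checksum per output file, so identical config + seed reproduces
byte-identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datatypes import FilterPolicy, MathPolicy, PatientProfile, filter_variants
from .diversity import compute_cohort_metrics, restrict_to_mss
from .errors import ConfigurationError, CtcDivError, InputError
from .io import load_cohort, read_gene_coords, read_gene_list
from .panels import add_panel_math_column, build_frequency_panel, panel_concordance, panel_survival
from .simulate import SimConfig, driver_gene_coords, simulate_cohort, write_cohort
from .survival import run_survival_analysis

logger = logging.getLogger(__name__)

CONTINUOUS_METRICS = ["age_years", "lines_of_treatment", "mb", "pag", "math",
                      "crc_mut", "crc_cna"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    out_dir: str
    seed: int = 0
    synthetic: SimConfig | None = None   # synthetic mode when set
    cohort_dir: str | None = None        # otherwise read real inputs here
    drivers_file: str | None = None
    driver_coords_file: str | None = None
    filter_policy: FilterPolicy = field(default_factory=FilterPolicy)
    math_policy: MathPolicy = field(default_factory=MathPolicy)
    min_patients_recurrent: int = 4
    min_group_fraction: float = 0.10
    alpha_include: float = 0.1
    panel_thresholds: tuple[int, ...] = (15, 10)
    panel_files: tuple[str, ...] = ()

    def validate(self) -> None:
        if self.synthetic is None:
            if self.cohort_dir is None:
                raise ConfigurationError(
                    "cohort_dir is required when no synthetic config is given")
            root = Path(self.cohort_dir)
            for required in ("clinical.tsv", "msi.tsv", "capture.bed"):
                if not (root / required).exists():
                    raise ConfigurationError(
                        f"missing input file: {root / required}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "synthetic" in data and data["synthetic"] is not None:
            data["synthetic"] = SimConfig.from_dict(data["synthetic"])
        if "filter_policy" in data:
            data["filter_policy"] = FilterPolicy(**data["filter_policy"])
        if "math_policy" in data:
            data["math_policy"] = MathPolicy(**data["math_policy"])
        for key in ("panel_thresholds", "panel_files"):
            if key in data:
                data[key] = tuple(data[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown run-config fields: {sorted(unknown)}")
        return cls(**data)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run manifest.

    Stages: (1) simulate or load the cohort and apply the genotype filter;
    (2) compute diversity metrics and MSI status; (3) restrict to MSS;
    (4) staged univariate/multivariate survival analysis; (5) build and
    evaluate gene panels. Any stage error halts the run; a partial manifest
    naming the failed stage is still written.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
    }
    stage = "setup"
    try:
        # stage 1: cohort
        stage = "cohort"
        if config.synthetic is not None:
            sim = dataclasses.replace(config.synthetic, seed=config.seed)
            cohort = simulate_cohort(sim)
            write_cohort(cohort, out / "cohort", sim)
            for p in cohort:
                kept, dropped = filter_variants(p.variants, config.filter_policy)
                logger.info("%s: %d variants kept, %d dropped by genotype filter",
                            p.patient_id, len(kept), dropped)
                p.variants = kept
            drivers = list(sim.driver_genes)
            coords = driver_gene_coords(sim.driver_genes)
            manifest["mode"] = "synthetic"
            manifest["config"] = sim.to_dict()
        else:
            cohort = load_cohort(config.cohort_dir, config.filter_policy)
            drivers = read_gene_list(config.drivers_file
                                     or Path(config.cohort_dir) / "drivers.txt")
            coords = read_gene_coords(config.driver_coords_file
                                      or Path(config.cohort_dir) / "driver_coords.tsv")
            manifest["mode"] = "input"
        manifest["stages"].append({"stage": stage, "n_patients": len(cohort)})

        # stage 2: metrics
        stage = "metrics"
        metrics = compute_cohort_metrics(
            cohort, drivers, coords, config.math_policy,
            config.min_patients_recurrent)
        _write_tsv(metrics, out / "metrics.tsv")
        manifest["stages"].append({"stage": stage, "n_rows": len(metrics)})

        # stage 3: MSS restriction (before any survival analysis)
        stage = "mss_restriction"
        mss_cohort = restrict_to_mss(cohort)
        mss_ids = {p.patient_id for p in mss_cohort}
        mss_metrics = metrics[metrics["patient_id"].isin(mss_ids)].reset_index(drop=True)
        manifest["stages"].append({
            "stage": stage, "n_mss": len(mss_cohort),
            "n_excluded_msi": len(cohort) - len(mss_cohort)})

        # stage 4: survival
        stage = "survival"
        gene_cols = [c for c in mss_metrics.columns if c.startswith("gene_")]
        report = run_survival_analysis(
            mss_metrics, CONTINUOUS_METRICS, gene_cols + ["sex"],
            alpha_include=config.alpha_include,
            min_group_fraction=config.min_group_fraction)
        _write_tsv(report.screen.table, out / "univariate.tsv")
        cut_df = pd.DataFrame([dataclasses.asdict(c)
                               for c in report.screen.cutoffs.values()])
        _write_tsv(cut_df, out / "cutoffs.tsv")
        if report.multivariate is not None:
            multi = report.multivariate.table.reset_index(names="covariate")
            _write_tsv(multi, out / "multivariate.tsv")
        if report.medians is not None:
            _write_tsv(report.medians, out / "km_medians.tsv")
        for var, curves in report.km.items():
            frames = []
            for label, est in curves.items():
                f = est.as_frame()
                f.insert(0, "stratum", label)
                frames.append(f)
            _write_tsv(pd.concat(frames, ignore_index=True),
                       out / f"km_{var}.tsv")
        manifest["stages"].append({"stage": stage,
                                   "selected": report.screen.selected,
                                   "notes": report.notes})

        # stage 5: panels
        stage = "panels"
        panel_rows = []
        panel_metrics = mss_metrics
        for threshold in config.panel_thresholds:
            try:
                panel = build_frequency_panel(mss_cohort, threshold)
            except CtcDivError as exc:
                logger.warning("panel threshold %d skipped: %s", threshold, exc)
                continue
            col = f"math_{panel.name}"
            panel_metrics = add_panel_math_column(panel_metrics, mss_cohort,
                                                  panel, col)
            nan = float("nan")
            row = {
                "panel": panel.name, "rule": panel.construction_rule,
                "n_genes": len(panel.genes),
                "concordance_r2": nan, "concordance_p": nan,
                "slope": nan, "intercept": nan,
                "hr_continuous": nan, "p_continuous": nan,
                "hr_binary": nan, "p_binary": nan, "cutoff": nan,
            }
            paired = panel_metrics.dropna(subset=[col, "math"])
            try:
                (row["concordance_r2"], row["concordance_p"],
                 row["slope"], row["intercept"]) = panel_concordance(
                    paired[col], paired["math"])
            except CtcDivError as exc:
                logger.warning("panel %s: concordance unavailable (%s)",
                               panel.name, exc)
            try:
                psurv = panel_survival(
                    panel_metrics.dropna(subset=[col]), col,
                    min_group_fraction=config.min_group_fraction)
                tab = psurv.screen.table.set_index("variable")
                if col in tab.index:
                    row["hr_continuous"] = tab.loc[col, "hr"]
                    row["p_continuous"] = tab.loc[col, "p"]
                bcol = f"b_{col}"
                if bcol in tab.index:
                    row["hr_binary"] = tab.loc[bcol, "hr"]
                    row["p_binary"] = tab.loc[bcol, "p"]
                    row["cutoff"] = tab.loc[bcol, "cutoff"]
            except CtcDivError as exc:
                logger.warning("panel %s: survival analysis unavailable (%s)",
                               panel.name, exc)
            panel_rows.append(row)
            (out / f"panel_{panel.name}.txt").write_text(
                "".join(f"{g}\n" for g in panel.genes))
        for panel_file in config.panel_files:
            genes = tuple(read_gene_list(panel_file))
            panel = build_panel_from_list(Path(panel_file).stem, genes)
            col = f"math_{panel.name}"
            panel_metrics = add_panel_math_column(panel_metrics, mss_cohort,
                                                  panel, col)
            paired = panel_metrics.dropna(subset=[col, "math"])
            if len(paired) >= 3:
                r2, pval, slope, intercept = panel_concordance(
                    paired[col], paired["math"])
            else:
                r2 = pval = slope = intercept = float("nan")
            panel_rows.append({
                "panel": panel.name, "rule": "user-supplied",
                "n_genes": len(panel.genes),
                "concordance_r2": r2, "concordance_p": pval,
                "slope": slope, "intercept": intercept,
            })
        _write_tsv(pd.DataFrame(panel_rows), out / "panels.tsv")
        _write_tsv(panel_metrics, out / "panel_metrics.tsv")
        manifest["stages"].append({"stage": stage,
                                   "panels": [r["panel"] for r in panel_rows]})
    except CtcDivError as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _finalize_manifest(manifest, out)
        raise
    _finalize_manifest(manifest, out)
    return manifest


def build_panel_from_list(name: str, genes: tuple[str, ...]):
    from .panels import PanelDef
    return PanelDef(name=name, genes=genes, construction_rule="user-supplied")


def _finalize_manifest(manifest: dict, out: Path) -> None:
    files = sorted(str(p.relative_to(out)) for p in out.rglob("*")
                   if p.is_file() and p.name != "run_manifest.json")
    manifest["files"] = {
        f: hashlib.sha256((out / f).read_bytes()).hexdigest() for f in files}
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
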