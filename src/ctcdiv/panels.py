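"""Gene-panel construction and panel-based diversity scoring.

Targeted panels are a cheap alternative to whole-exome sequencing for
estimating CTC-pool heterogeneity. Frequency-based panels collect the
cohort's most frequently mutated genes (total variant records across
patients strictly above a threshold); the MATH score is then recomputed on
panel-restricted variants *without* read-count filters, since panels leave
few variants per patient. Concordance with exome-wide MATH is summarised by
an ordinary least-squares fit, and the panel score's association with
survival reuses the survival module (continuous and optimal-cutoff binary
forms).

A panel built and evaluated on the same cohort that defined its gene
frequencies inherits an ascertainment bias; conclusions about its
prognostic value require an independent cohort.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import NONSILENT, MathPolicy, PatientProfile, VariantCall
from .diversity import math_score
from .errors import AnalysisError
from .survival import SurvivalReport, run_survival_analysis

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PanelDef:
    """A named gene panel."""

    name: str
    genes: tuple[str, ...]
    construction_rule: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise AnalysisError(f"panel {self.name!r} has an empty gene list")
        norm = [g.strip().upper() for g in self.genes]
        if len(set(norm)) != len(norm):
            raise AnalysisError(f"panel {self.name!r} has duplicate gene symbols")

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(g.strip().upper() for g in self.genes)


def build_frequency_panel(cohort: list[PatientProfile], min_mutations: int,
                          name: str | None = None,
                          nonsilent_only: bool = False) -> PanelDef:
    """Genes with strictly more than ``min_mutations`` variant records
    summed across patients (all post-filter SNVs and indels by default)."""
    if min_mutations < 1:
        raise AnalysisError("min_mutations must be >= 1")
    counts: Counter[str] = Counter()
    for p in cohort:
        for v in p.variants:
            if not v.gene:
                continue
            if nonsilent_only and v.consequence != NONSILENT:
                continue
            counts[v.gene.strip().upper()] += 1
    genes = tuple(sorted(g for g, c in counts.items() if c > min_mutations))
    if not genes:
        raise AnalysisError(
            f"no gene exceeds {min_mutations} mutations across the cohort")
    if name is None:
        name = f"CRC-P{len(genes)}"
    return PanelDef(name=name, genes=genes,
                    construction_rule=f"count > {min_mutations}")


# no depth filter: panels leave too few variants per patient
PANEL_MATH_POLICY = MathPolicy(apply_depth_filter=False)


def panel_math(variants: list[VariantCall], panel: PanelDef) -> float | None:
    """MATH on panel-gene variants, no read-count filter; None if < 3 variants."""
    panel_genes = panel.gene_set
    sub = [v for v in variants if v.gene.strip().upper() in panel_genes]
    score = math_score(sub, PANEL_MATH_POLICY)
    if score is None:
        logger.info("panel %s: only %d variants for this patient; MATH missing",
                    panel.name, len(sub))
    return score


def panel_concordance(panel_math_values, wes_math_values
                      ) -> tuple[float, float, float, float]:
    """OLS of panel MATH on exome MATH: (r_squared, p, slope, intercept).

    Pairs with a missing value on either side are dropped; at least 3
    complete pairs are required.
    """
    x = np.asarray(wes_math_values, dtype=float)
    y = np.asarray(panel_math_values, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise AnalysisError(f"need >= 3 paired MATH values, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("zero variance in one of the MATH vectors")
    res = stats.linregress(x, y)
    return (float(res.rvalue ** 2), float(res.pvalue),
            float(res.slope), float(res.intercept))


def panel_survival(metrics_df: pd.DataFrame, panel_math_col: str,
                   duration_col: str = "os_months", event_col: str = "event",
                   min_group_fraction: float = 0.10) -> SurvivalReport:
    """Univariate association of a panel MATH score with overall survival.

    Fits continuous panel MATH and its optimal-cutoff Low/High split,
    with Kaplan–Meier medians per stratum. ``metrics_df`` must be the
    MSS-restricted table with the panel score in ``panel_math_col``.
    """
    if len(metrics_df) < 2:
        raise AnalysisError("panel survival analysis needs at least 2 patients")
    return run_survival_analysis(
        metrics_df, continuous_metrics=[panel_math_col], binary_metrics=[],
        duration_col=duration_col, event_col=event_col,
        alpha_include=0.05, min_group_fraction=min_group_fraction)


def add_panel_math_column(metrics_df: pd.DataFrame,
                          cohort: list[PatientProfile],
                          panel: PanelDef, column: str) -> pd.DataFrame:
    """Attach a per-patient panel MATH column to the metric table."""
    scores = {p.patient_id: panel_math(p.variants, panel) for p in cohort}
    out = metrics_df.copy()
    out[column] = out["patient_id"].map(
        lambda pid: np.nan if scores.get(pid) is None else scores[pid])
    return out
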