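"""Survival machinery: log-rank, Kaplan–Meier, Cox fits, optimal cutoffs.

The analysis correlates per-patient diversity metrics with overall survival
in two stages. Each metric is first screened univariately with a Cox
proportional-hazards fit — continuous metrics on their raw scale and as a
binary Low/High split at the *optimal cutoff*, i.e. the threshold whose
induced two-group split minimises the log-rank p-value (the CutoffFinder
procedure; inherently multiplicity-inflated, which the calibration tests
document). Metrics with a univariate p <= 0.1 enter the multivariate model;
when both the continuous and binary forms of a metric pass, only the
continuous form is carried forward. Reference levels for binary covariates
are Low / unmutated / female (coded 0).

The two-group log-rank statistic is computed here directly from risk-set
tabulation (it is the inner loop of the cutoff scan, evaluated over a grid
of candidate splits); Kaplan–Meier estimation and partial-likelihood
maximisation (Efron tie handling) are delegated to lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .errors import AnalysisError

logger = logging.getLogger(__name__)

LOW, HIGH = "Low", "High"


# ---------------------------------------------------------------------------
# log-rank

def _logrank_grid(times: np.ndarray, events: np.ndarray,
                  group_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-group log-rank statistics for many candidate group assignments.

    ``group_matrix`` has one row per candidate split (True = group 1). At
    each distinct event time the observed minus expected group-1 events and
    the hypergeometric variance are accumulated; the statistic is
    ``(sum(O - E))^2 / sum(V)`` on 1 df.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    G = np.asarray(group_matrix, dtype=float)
    event_times = np.unique(t[e == 1])
    # masks over patients, one row per distinct event time
    at_risk = t[None, :] >= event_times[:, None]              # T x n
    dying = (t[None, :] == event_times[:, None]) & (e[None, :] == 1)
    n_risk = at_risk.sum(axis=1).astype(float)                # T
    d = dying.sum(axis=1).astype(float)                       # T
    n1 = G @ at_risk.T.astype(float)                          # C x T
    d1 = G @ dying.T.astype(float)                            # C x T
    frac = n1 / n_risk
    expected = d * frac
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(n_risk > 1,
                       d * frac * (1.0 - frac) * (n_risk - d) / (n_risk - 1.0),
                       0.0)
    num = (d1 - expected).sum(axis=1) ** 2
    den = var.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(den > 0, num / den, 0.0)
    p = stats.chi2.sf(chi2, df=1)
    # a split with zero variance (e.g. all events shared) carries no signal
    p = np.where(den > 0, p, 1.0)
    return chi2, p


def logrank_test(times, events, group_labels) -> tuple[float, float]:
    """Standard two-group log-rank test (1 df).

    ``group_labels`` must take exactly two values, both non-empty, and at
    least one event must be observed.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(group_labels)
    if len(t) != len(e) or len(t) != len(g):
        raise AnalysisError("times, events and group_labels must align")
    labels = np.unique(g)
    if len(labels) != 2:
        raise AnalysisError(f"log-rank needs exactly 2 non-empty groups, got {len(labels)}")
    if e.sum() == 0:
        raise AnalysisError("log-rank undefined with zero events")
    chi2, p = _logrank_grid(t, e, (g == labels[1])[None, :])
    return float(chi2[0]), float(p[0])


# ---------------------------------------------------------------------------
# Kaplan–Meier

@dataclass
class KMEstimate:
    """Product-limit survival curve with Greenwood-based 95% band."""

    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float  # np.inf when the curve never reaches 0.5
    n: int
    n_events: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "survival": self.survival,
            "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
        })


def kaplan_meier(times, events) -> KMEstimate:
    """Kaplan–Meier estimate; median = earliest time with survival <= 0.5."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) == 0:
        raise AnalysisError("kaplan_meier needs at least one patient")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_["KM_estimate"]
    ci = kmf.confidence_interval_
    return KMEstimate(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.to_numpy(dtype=float),
        ci_lower=ci.iloc[:, 0].to_numpy(dtype=float),
        ci_upper=ci.iloc[:, 1].to_numpy(dtype=float),
        median=float(kmf.median_survival_time_),
        n=len(t), n_events=int(e.sum()),
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards

@dataclass
class CoxFit:
    """Hazard ratios with Wald 95% CIs and p-values for one fitted model."""

    table: pd.DataFrame  # index: covariate; columns: coef, se, hr, ci_low, ci_high, p
    n: int
    n_events: int
    log_likelihood: float

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])

    def p(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "p"])


def fit_cox(df: pd.DataFrame, covariates: list[str],
            duration_col: str = "os_months", event_col: str = "event") -> CoxFit:
    """Cox proportional-hazards fit (Efron tie handling via lifelines).

    Rows with missing covariate values are dropped pairwise; binary
    covariates are expected pre-coded with the reference level as 0.
    """
    cols = [duration_col, event_col] + list(covariates)
    sub = df[cols].dropna()
    n_dropped = len(df) - len(sub)
    if n_dropped:
        logger.info("fit_cox: dropped %d rows with missing values", n_dropped)
    n_events = int(sub[event_col].sum())
    if n_events < len(covariates):
        raise AnalysisError(
            f"{n_events} events < {len(covariates)} covariates; model unidentifiable")
    for c in covariates:
        if sub[c].nunique() < 2:
            raise AnalysisError(f"covariate {c!r} is constant after row filtering")
    cph = CoxPHFitter()
    try:
        cph.fit(sub, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as exc:
        raise AnalysisError(
            f"Cox model failed to converge for {covariates}: {exc}") from exc
    s = cph.summary
    table = pd.DataFrame({
        "coef": s["coef"],
        "se": s["se(coef)"],
        "hr": s["exp(coef)"],
        "ci_low": s["exp(coef) lower 95%"],
        "ci_high": s["exp(coef) upper 95%"],
        "p": s["p"],
    })
    return CoxFit(table=table, n=len(sub), n_events=n_events,
                  log_likelihood=float(cph.log_likelihood_))


# ---------------------------------------------------------------------------
# optimal cutoff

@dataclass
class CutoffResult:
    variable: str
    cutoff: float
    chi_square: float
    p_value: float
    n_low: int
    n_high: int


def find_optimal_cutoff(times, events, values, variable: str = "",
                        min_group_fraction: float = 0.10) -> CutoffResult:
    """Optimal dichotomisation of a continuous marker by log-rank p-value.

    Candidate cutoffs are midpoints between consecutive distinct observed
    values; candidates leaving either group smaller than
    ``min_group_fraction * n`` are excluded. Returns the candidate with the
    smallest log-rank p; ties go to the cutoff closest to the marker median.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise AnalysisError("cutoff scan requires non-missing marker values")
    distinct = np.unique(x)
    if distinct.size < 2:
        raise AnalysisError(f"{variable or 'marker'} has < 2 distinct values")
    if e.sum() == 0:
        raise AnalysisError("cutoff scan undefined with zero events")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    n = len(x)
    high = x[None, :] > candidates[:, None]          # C x n
    n_high = high.sum(axis=1)
    min_n = min_group_fraction * n
    admissible = (n_high >= min_n) & ((n - n_high) >= min_n)
    if not admissible.any():
        raise AnalysisError(
            f"no admissible cutoff for {variable or 'marker'} at "
            f"min_group_fraction={min_group_fraction}")
    candidates = candidates[admissible]
    high = high[admissible]
    n_high = n_high[admissible]
    chi2, p = _logrank_grid(t, e, high)
    p_min = p.min()
    tied = np.flatnonzero(p <= p_min * (1 + 1e-12) + 1e-300)
    med = float(np.median(x))
    best = tied[np.lexsort((candidates[tied], np.abs(candidates[tied] - med)))[0]]
    return CutoffResult(
        variable=variable, cutoff=float(candidates[best]),
        chi_square=float(chi2[best]), p_value=float(p[best]),
        n_low=int(n - n_high[best]), n_high=int(n_high[best]),
    )


# ---------------------------------------------------------------------------
# staged univariate -> multivariate analysis

def encode_binary_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Code reference levels as 0: female=0/male=1, unmutated=0/mutated=1."""
    out = df.copy()
    if "sex" in out.columns and out["sex"].dtype == object:
        out["sex"] = out["sex"].map({"female": 0, "male": 1})
    for col in out.columns:
        if col.startswith("gene_") and out[col].dtype == object:
            out[col] = out[col].map({"unmutated": 0, "mutated": 1})
    return out


@dataclass
class ScreenResult:
    """Univariate screen: per-form fits, cutoffs, and the selected set."""

    table: pd.DataFrame
    cutoffs: dict[str, CutoffResult]
    selected: list[str]          # column names in `frame` entering the multivariate fit
    frame: pd.DataFrame          # input frame augmented with b_<metric> columns


def univariate_screen(df: pd.DataFrame, continuous_metrics: list[str],
                      binary_metrics: list[str] | None = None,
                      duration_col: str = "os_months", event_col: str = "event",
                      alpha_include: float = 0.1,
                      min_group_fraction: float = 0.10) -> ScreenResult:
    """One univariate Cox fit per metric form; select forms with p <= alpha.

    Continuous metrics are fitted raw and as the Low/High split at their
    optimal cutoff (High coded 1); when both forms pass the threshold only
    the continuous form is selected. ``binary_metrics`` are intrinsic 0/1
    covariates (gene status, sex) fitted once.
    """
    binary_metrics = binary_metrics or []
    frame = encode_binary_covariates(df)
    rows = []
    cutoffs: dict[str, CutoffResult] = {}
    selected: list[str] = []

    for m in continuous_metrics:
        sub = frame.dropna(subset=[m])
        n_missing = len(frame) - len(sub)
        if n_missing:
            logger.info("screen: %s missing for %d patients", m, n_missing)
        try:
            fit_c = fit_cox(sub, [m], duration_col, event_col)
        except AnalysisError as exc:
            logger.warning("screen: skipping %s (%s)", m, exc)
            continue
        rows.append({"variable": m, "form": "continuous", "n": fit_c.n,
                     "hr": fit_c.hr(m), "ci_low": fit_c.table.loc[m, "ci_low"],
                     "ci_high": fit_c.table.loc[m, "ci_high"], "p": fit_c.p(m),
                     "cutoff": np.nan})
        try:
            cut = find_optimal_cutoff(
                sub[duration_col], sub[event_col], sub[m],
                variable=m, min_group_fraction=min_group_fraction)
        except AnalysisError as exc:
            logger.warning("screen: no cutoff for %s (%s)", m, exc)
            if fit_c.p(m) <= alpha_include:
                selected.append(m)
            continue
        cutoffs[m] = cut
        bname = f"b_{m}"
        frame[bname] = np.where(frame[m].isna(), np.nan,
                                (frame[m] > cut.cutoff).astype(float))
        try:
            fit_b = fit_cox(frame.dropna(subset=[bname]), [bname],
                            duration_col, event_col)
        except AnalysisError as exc:
            logger.warning("screen: binary form of %s unfittable (%s)", m, exc)
            fit_b = None
        if fit_b is not None:
            rows.append({"variable": bname, "form": "binary", "n": fit_b.n,
                         "hr": fit_b.hr(bname),
                         "ci_low": fit_b.table.loc[bname, "ci_low"],
                         "ci_high": fit_b.table.loc[bname, "ci_high"],
                         "p": fit_b.p(bname), "cutoff": cut.cutoff})
        # continuous preferred when both forms pass
        if fit_c.p(m) <= alpha_include:
            selected.append(m)
        elif fit_b is not None and fit_b.p(bname) <= alpha_include:
            selected.append(bname)

    for m in binary_metrics:
        sub = frame.dropna(subset=[m])
        if sub[m].nunique() < 2:
            logger.info("screen: %s constant, skipped", m)
            continue
        try:
            fit = fit_cox(sub, [m], duration_col, event_col)
        except AnalysisError as exc:
            logger.warning("screen: skipping %s (%s)", m, exc)
            continue
        rows.append({"variable": m, "form": "binary", "n": fit.n,
                     "hr": fit.hr(m), "ci_low": fit.table.loc[m, "ci_low"],
                     "ci_high": fit.table.loc[m, "ci_high"], "p": fit.p(m),
                     "cutoff": np.nan})
        if fit.p(m) <= alpha_include:
            selected.append(m)

    table = pd.DataFrame(rows)
    return ScreenResult(table=table, cutoffs=cutoffs, selected=selected,
                        frame=frame)


@dataclass
class SurvivalReport:
    """End-to-end survival analysis: screen, multivariate fit, KM curves."""

    screen: ScreenResult
    multivariate: CoxFit | None
    km: dict[str, dict[str, KMEstimate]] = field(default_factory=dict)
    medians: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)


def run_survival_analysis(df: pd.DataFrame, continuous_metrics: list[str],
                          binary_metrics: list[str] | None = None,
                          duration_col: str = "os_months",
                          event_col: str = "event",
                          alpha_include: float = 0.1,
                          min_group_fraction: float = 0.10) -> SurvivalReport:
    """Cutoffs -> univariate screen -> multivariate model -> KM curves.

    Expects an MSS-restricted metric table (one row per patient). KM curves
    and median survival are reported per stratum of every binary variable
    tied to the selected set (selected continuous metrics are stratified at
    their optimal cutoff for display).
    """
    if df[event_col].sum() == 0:
        raise AnalysisError("no events observed; survival analysis undefined")
    screen = univariate_screen(df, continuous_metrics, binary_metrics,
                               duration_col, event_col, alpha_include,
                               min_group_fraction)
    notes = [f"univariate screen: {len(screen.table)} tests, "
             f"{len(screen.selected)} selected at p<={alpha_include}"]

    multivariate = None
    if screen.selected:
        try:
            multivariate = fit_cox(screen.frame, screen.selected,
                                   duration_col, event_col)
        except AnalysisError as exc:
            notes.append(f"multivariate fit failed: {exc}")
    else:
        notes.append("no metric passed the univariate screen; "
                     "reporting univariate results only")

    km: dict[str, dict[str, KMEstimate]] = {}
    med_rows = []
    for var in screen.selected:
        strat = var if screen.frame[var].dropna().isin([0, 1]).all() \
            else f"b_{var}"
        if strat not in screen.frame.columns:
            continue
        sub = screen.frame.dropna(subset=[strat])
        curves = {}
        for value, label in ((0.0, LOW), (1.0, HIGH)):
            grp = sub[sub[strat] == value]
            if len(grp) == 0:
                continue
            est = kaplan_meier(grp[duration_col], grp[event_col])
            curves[label] = est
            med_rows.append({"variable": strat, "stratum": label,
                             "n": est.n, "n_events": est.n_events,
                             "median_os_months": est.median})
        km[strat] = curves
    medians = pd.DataFrame(med_rows) if med_rows else None
    return SurvivalReport(screen=screen, multivariate=multivariate,
                          km=km, medians=medians, notes=notes)
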