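"""Staged survival analysis of the diversity metrics.

On the MSS-restricted metric table: optimal-cutoff dichotomization of each
continuous metric, univariate Cox screen at p <= 0.1 (continuous preferred
over binary when both pass), multivariate Cox fit on the selected set, and
Kaplan-Meier medians per stratum. Tables go to results/survival/.
"""

from pathlib import Path

import pandas as pd

from ctcdiv.pipeline import CONTINUOUS_METRICS
from ctcdiv.survival import run_survival_analysis


def main() -> None:
    metrics = pd.read_csv("results/metrics.tsv", sep="\t")
    mss = metrics[metrics["msi_status"] == "MSS"].reset_index(drop=True)
    gene_cols = [c for c in mss.columns if c.startswith("gene_")]
    report = run_survival_analysis(mss, CONTINUOUS_METRICS, gene_cols + ["sex"])

    out = Path("results/survival")
    out.mkdir(parents=True, exist_ok=True)
    report.screen.table.to_csv(out / "univariate.tsv", sep="\t", index=False,
                               float_format="%.6g")
    cuts = pd.DataFrame([vars(c) for c in report.screen.cutoffs.values()])
    cuts.to_csv(out / "cutoffs.tsv", sep="\t", index=False, float_format="%.6g")
    print(f"univariate screen: {len(report.screen.table)} tests "
          f"({len(mss)} MSS patients)")
    print(f"selected at p<=0.1: {report.screen.selected or 'none'}")
    if report.multivariate is not None:
        tab = report.multivariate.table
        tab.reset_index(names="covariate").to_csv(
            out / "multivariate.tsv", sep="\t", index=False, float_format="%.6g")
        print("multivariate hazard ratios:")
        for cov, row in tab.iterrows():
            print(f"  {cov:22s} HR={row['hr']:.2f} "
                  f"({row['ci_low']:.2f}-{row['ci_high']:.2f}) p={row['p']:.4f}")
    if report.medians is not None:
        report.medians.to_csv(out / "km_medians.tsv", sep="\t", index=False,
                              float_format="%.6g")
        print("median OS per stratum:")
        for _, r in report.medians.iterrows():
            print(f"  {r['variable']} {r['stratum']}: "
                  f"{r['median_os_months']:.1f} months (n={r['n']})")


if __name__ == "__main__":
    main()
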