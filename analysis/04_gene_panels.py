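"""Frequency-based gene panels as a low-cost surrogate for exome MATH.

Builds panels from genes with > 15 and > 10 mutations across the MSS
cohort, recomputes MATH on panel-restricted variants without read-count
filters, measures concordance with exome-wide MATH (OLS R^2), and tests the
panel scores against overall survival. Caveat: a panel built and evaluated
on the same cohort inherits an ascertainment bias.
"""

from pathlib import Path

import pandas as pd

from ctcdiv.datatypes import FilterPolicy, MathPolicy
from ctcdiv.diversity import compute_cohort_metrics, restrict_to_mss
from ctcdiv.io import load_cohort, read_gene_coords, read_gene_list
from ctcdiv.panels import add_panel_math_column, build_frequency_panel, panel_concordance, panel_survival


def main() -> None:
    root = Path("scratch/cohort")
    cohort = restrict_to_mss(load_cohort(root, FilterPolicy()))
    drivers = read_gene_list(root / "drivers.txt")
    coords = read_gene_coords(root / "driver_coords.tsv")
    table = compute_cohort_metrics(cohort, drivers, coords, MathPolicy())

    out = Path("results/panels")
    out.mkdir(parents=True, exist_ok=True)
    for threshold in (15, 10):
        panel = build_frequency_panel(cohort, threshold)
        col = f"math_{panel.name}"
        table = add_panel_math_column(table, cohort, panel, col)
        (out / f"{panel.name}.txt").write_text(
            "".join(f"{g}\n" for g in panel.genes))
        paired = table.dropna(subset=[col, "math"])
        r2, pval, slope, _ = panel_concordance(paired[col], paired["math"])
        print(f"{panel.name} ({panel.construction_rule}): "
              f"{len(panel.genes)} genes")
        print(f"  concordance with WES MATH: R^2={r2:.3f} "
              f"(slope {slope:.2f}, p={pval:.2g}, n={len(paired)})")
        try:
            rep = panel_survival(table.dropna(subset=[col]), col)
            tab = rep.screen.table.set_index("variable")
            print(f"  survival: continuous HR={tab.loc[col, 'hr']:.3f} "
                  f"p={tab.loc[col, 'p']:.3f}; "
                  f"binary HR={tab.loc[f'b_{col}', 'hr']:.2f} "
                  f"p={tab.loc[f'b_{col}', 'p']:.3f}")
        except Exception as exc:  # small cohorts can defeat the binary fit
            print(f"  survival analysis unavailable: {exc}")
    table.to_csv(out / "panel_metrics.tsv", sep="\t", index=False,
                 float_format="%.6g")
    print("panel metric table -> results/panels/panel_metrics.tsv")


if __name__ == "__main__":
    main()
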