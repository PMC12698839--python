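"""Compute per-patient diversity metrics for the reference cohort.

Reads scratch/cohort/ (written by 01_simulate_cohort.py), applies the
genotype filter (>=10 total reads, >=2 alternate reads, VAF > 0.075),
computes MB, PAG, MATH, driver-gene burdens, recurrent gene status and MSI
status, and writes results/metrics.tsv.
"""

from pathlib import Path

from ctcdiv.datatypes import FilterPolicy, MathPolicy
from ctcdiv.diversity import compute_cohort_metrics
from ctcdiv.io import load_cohort, read_gene_coords, read_gene_list


def main() -> None:
    root = Path("scratch/cohort")
    if not root.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    cohort = load_cohort(root, FilterPolicy())
    drivers = read_gene_list(root / "drivers.txt")
    coords = read_gene_coords(root / "driver_coords.tsv")
    metrics = compute_cohort_metrics(cohort, drivers, coords, MathPolicy())
    metrics.to_csv("results/metrics.tsv", sep="\t", index=False,
                   float_format="%.6g")
    mss = metrics[metrics["msi_status"] == "MSS"]
    print(f"metrics for {len(metrics)} patients -> results/metrics.tsv")
    print(f"  MSS: {len(mss)}  (MSI excluded from survival analyses)")
    print(f"  MB   [SNVs/Mb]: {mss['mb'].min():.2f}-{mss['mb'].max():.2f}")
    print(f"  PAG           : {mss['pag'].min():.3f}-{mss['pag'].max():.3f}")
    print(f"  MATH          : {mss['math'].min():.1f}-{mss['math'].max():.1f}")
    genes = [c for c in metrics.columns if c.startswith("gene_")]
    print(f"  recurrent driver genes (>=4 patients): {len(genes)}")


if __name__ == "__main__":
    main()
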