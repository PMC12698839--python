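"""Generate the reference synthetic cohort.

Draws the default 29-patient metastatic-CRC cohort (clonal + subclonal VAF
mixtures, overdispersed depths, CNA segments, an expected single MSI
patient, survival under planted hazards) and writes it in the pipeline's
input formats under scratch/cohort/.
"""

from ctcdiv.simulate import SimConfig, simulate_cohort, write_cohort

SEED = 1


def main() -> None:
    cfg = SimConfig(seed=SEED)
    cohort = simulate_cohort(cfg)
    manifest = write_cohort(cohort, "scratch/cohort", cfg)
    n_msi = sum(p.msi_fraction > 0.30 for p in cohort)
    n_variants = [len(p.variants) for p in cohort]
    print(f"wrote {manifest['n_patients']} patients to scratch/cohort/")
    print(f"  variants per patient: {min(n_variants)}-{max(n_variants)}")
    print(f"  MSI patients: {n_msi}")
    print(f"  files: {len(manifest['files'])} (checksummed in manifest.json)")


if __name__ == "__main__":
    main()
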