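#!/usr/bin/env python
"""Generate the study cohort and verify the planted clinical effects.

Writes a 294-participant synthetic cohort (185 PD / 72 HC / 37 SWEDD) with
the full reported pathway-outcome effect matrix planted through the Gaussian
copula, then checks every planted Spearman correlation against its target.

Outputs under results/cohort/: features.csv, clinical.csv, truth.json and
planting_report.csv. Typical finding: every bootstrap CI covers its target
(the realized correlations at n=294 scatter around the planted values with
SE ~ 0.06).
"""

from pathlib import Path

from pathstrat.synthetic import (SyntheticConfig, generate_cohort,
                                 verify_planting, write_cohort)

OUT = Path("results/cohort")
SEED = 20250920


def main() -> None:
    cfg = SyntheticConfig(seed=SEED)
    fm, clinical, truth = generate_cohort(cfg)
    paths = write_cohort(fm, clinical, truth, OUT)
    report = verify_planting(fm, clinical, truth, n_boot=1000, seed=SEED)
    report.to_csv(OUT / "planting_report.csv", index=False)

    print(f"cohort: {fm.n_subjects} subjects x {fm.n_features} columns")
    print(clinical.data["diagnosis"].value_counts().to_string())
    n_flagged = int(report["ci_excludes_target"].sum())
    print(f"\nplanted effects: {len(report)}; CIs excluding target: {n_flagged}")
    print(report.round(3).to_string(index=False))
    print(f"\nwrote {', '.join(str(p) for p in paths.values())}")


if __name__ == "__main__":
    main()
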