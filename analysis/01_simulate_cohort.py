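"""Simulate the study-sized cohort and check realized predictor moments.

Draws a 99-subject cohort under the published predictor means/SDs and the
fitted-model odds ratios (high-outcome prevalence 1/3), writes the subject
table and ground truth to results/, and prints realized vs configured
moments for the outcome-model predictors.
"""

import json
from pathlib import Path

from ptssrisk.cohort import CohortConfig, TABLE1_MOMENTS, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(exist_ok=True)
    cfg = CohortConfig(n=99, seed=1)
    table, truth = generate_cohort(cfg)
    table.to_csv(OUT / "cohort.csv", index=False)
    (OUT / "cohort_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))

    print(f"simulated cohort: n = {len(table)}, prevalence target = {cfg.prevalence:.3f}")
    print(f"realized high-IESR fraction:  {sum(truth['high_iesr']) / len(table):.3f}")
    print(f"realized high-PP fraction:    {sum(truth['high_pp']) / len(table):.3f}")
    print("\npredictor            configured (M, SD)    realized (M, SD)")
    for name in ("est_iq", "bdi", "emg_diff_ext", "sc_mean_response"):
        m, sd = TABLE1_MOMENTS[name]
        col = table[name].dropna()
        print(f"{name:<20} {m:>7.2f} {sd:>6.2f}      {col.mean():>7.2f} {col.std():>6.2f}")
    miss = table.filter(TABLE1_MOMENTS).isna().mean().mean()
    print(f"\nmean predictor missingness (MCAR): {miss:.3f} (configured {cfg.missing_rate})")
    print(f"wrote {OUT/'cohort.csv'} and {OUT/'cohort_truth.json'}")


if __name__ == "__main__":
    main()
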