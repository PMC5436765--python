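#!/usr/bin/env python
"""Generate a synthetic animal cohort and run the group comparison.

Emulates the in-vivo design: 3 control, 4 sham and 4 kindled "animals",
each measured on the 31-sample variant-B schedule with 4.1% assay CV.
Writes the tidy cohort to results/cohort.csv and the pooled one-way ANOVA
to results/cohort_summary.json.
"""

import json
from dataclasses import asdict
from pathlib import Path

import hpaxis

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)
MASTER_SEED = 20260927


def main() -> None:
    trajectories = {
        "control": hpaxis.integrate(hpaxis.control_scenario(days=3)),
        "sham": hpaxis.integrate(hpaxis.sham_scenario(days=3)),
        "kindled": hpaxis.integrate(hpaxis.lhk_scenario(days=3)),
    }
    cohort = hpaxis.make_cohort(
        trajectories,
        n_per_group={"control": 3, "sham": 4, "kindled": 4},
        noise=hpaxis.NoiseModel(cv=0.041, missingness_prob=0.05),
        master_seed=MASTER_SEED,
    )
    df = hpaxis.cohort_to_frame(cohort)
    df.to_csv(RESULTS / "cohort.csv", index=False, float_format="%.6g")

    anova = hpaxis.group_comparison(cohort)
    group_means = df.groupby("group")["value_ng_ml"].mean().to_dict()
    summary = {
        "master_seed": MASTER_SEED,
        "n_animals": len(cohort),
        "n_missing_samples": int(df["missing"].sum()),
        "group_mean_ng_ml": group_means,
        "anova": asdict(anova),
    }
    (RESULTS / "cohort_summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    print(f"{len(cohort)} animals, {summary['n_missing_samples']} lost samples")
    for g, v in group_means.items():
        print(f"  {g:8s} mean {v:8.1f} ng/mL")
    print(f"one-way ANOVA: F({anova.df_between},{anova.df_within}) = "
          f"{anova.F:.1f}, p = {anova.p_value:.2e}")
    print("\nFinding: pooled group means order kindled > sham > control and "
          "the ANOVA strongly rejects equality.  The kindled mean is inflated "
          "by the six 10-min samples riding the kindling spike; means over "
          "the shared hourly samples are much closer between groups.")


if __name__ == "__main__":
    main()
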