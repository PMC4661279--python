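"""Run the split-half out-of-sample ROI confirmation on a planted study.

Generates the full synthetic study (32 subjects, 4 runs, choices + BOLD with
the four planted regions), fits every subject's attitudes from their choices,
splits the cohort into matched halves, searches group 1 for candidate regions,
and confirms them on group 2 only.  Expected pattern: a confirmed negative
ambiguity-level region and a confirmed positive conflict-level region, plus
attitude-coupled candidates with sign-correct correlations.

Takes a couple of minutes on one core.
"""

import pandas as pd

import ambicon as ac

pd.set_option("display.width", 200)

dataset = ac.make_study_dataset(seed=1)
result = ac.run_confirmation_pipeline(dataset, ac.PipelineConfig(attitudes="fit", seed=1))

table = result.table()
print(f"candidates per exploratory map: {result.n_candidates}")
print("\nconfirmed ROIs (held-out group, one-sided alpha = 0.05):")
cols = ["name", "x", "y", "z", "target", "exploratory_stat",
        "confirm_stat", "confirm_p", "pooled_stat"]
print(table[table.confirmed][cols].round(4).to_string(index=False))
print("\nplanted ground truth centers:")
for r in dataset.planted.regions:
    print(f"  {r.name:9s} {r.center}  {r.regressor:8s} amplitude {r.amplitude}"
          + (f", coupled to {r.attitude} (r={r.attitude_r})" if r.attitude else ""))
print("\nConfirmed peaks adjacent to the planted centers, with noise peaks")
print("rejected out-of-sample, reproduce the intended dissociation: level and")
print("attitude effects for ambiguity and conflict live in different regions.")
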