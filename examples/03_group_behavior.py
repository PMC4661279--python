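"""Simulate the full 32-subject behavioral study and run the group statistics.

Each subject's choices are generated from their own attitudes (gamma_C mean
1.69 across the population - conflict averse; gamma_A mean 0.85 - ambiguity
seeking), fitted by MLE, summarized with the 3-SD outlier rule, one-sample
t-tests reported with d = t/sqrt(n), and attitude correlations using
ln(gamma_A).
"""

import numpy as np
import pandas as pd

import ambicon as ac

gambles = ac.generate_gamble_set(seed=0)
session = ac.build_session(gambles, seed=0, n_runs=4, volumes_per_run=120)
cohort = ac.sample_population(ac.PopulationSpec(seed=1))

rows = []
for i, subj in enumerate(cohort):
    choices = ac.simulate_choices(subj, session, seed=100 + i)
    fit = ac.fit_subject(choices, seed=i)
    ra, aa, ca = ac.model_free_attitudes(choices)
    rows.append({"ra": ra, "aa": aa, "ca": ca,
                 "gamma_a": fit.params.gamma_a, "gamma_c": fit.params.gamma_c})

tests, corr, excluded = ac.attitude_summary(pd.DataFrame(rows))
print(f"excluded as outliers: {len(excluded)} subject(s)")
print("\ngroup tests (gamma_c vs 1, ln gamma_a vs 0, bet scores vs 0):")
print(tests.round(3).to_string())
print("\nattitude correlations (ln gamma_A used for ambiguity):")
print(corr.round(2).to_string())
print("\nA positive, significant gamma_c row is group conflict aversion; the")
print("ln_gamma_a/gamma_c correlation shows whether the two attitudes travel")
print("together across subjects (they need not).")
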