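# ambicon

Decision making under **ambiguity** (imprecise probability information) versus
**informational conflict** (two precise but disagreeing sources) — a tested,
end-to-end re-implementation of the behavioral and neural analysis stack for a
matched-gamble fMRI study of this contrast, exercised on synthetic data with
known ground truth.

It is written for computational cognitive neuroscientists and neuroeconomists
who want to (a) analyse card-deck gamble tasks of this family, (b) validate
the statistical pipeline — choice model fitting, first-level GLM, split-half
out-of-sample ROI confirmation — against planted effects, or (c) run power and
calibration studies before collecting data.

## The task and the model

Each trial offers $3 for sure or a $10 bet on the type of a card drawn from a
100-card deck. A known number of Type-1 cards leaves `L` cards (the *level*,
6–94) split between Types 2 and 3. Under **risk** the split is known and
equal; under **ambiguity** only `L` is known; under **conflict** two equally
credible sources assert opposite precise splits. Conditions are matched on
expected value: a Type-2 bet wins with probability `L/200` everywhere.

Choices follow a subjective-expected-utility multinomial logit. Option *j*
with payoff `x_j` and winning probability `π_j` gets the weight

    W_j = x_j^θ · π_j^γ

where `θ` is the monetary-utility exponent and `γ` a condition-specific
probability-weighting parameter applied to the uncertain options (`γ = 1` for
risk, identifying the model; `γ_A`, `γ_C`, `γ_I` for ambiguity, conflict,
ignorance). Choice probabilities are `p_j = exp(W_j) / Σ_k exp(W_k)`; `γ > 1`
reads as aversion, `γ < 1` as seeking. Model-free scores count bets:
`RA = 10 − bets(risk)` (ten is the risk-neutral benchmark),
`AA = bets(risk) − bets(ambiguity)`, `CA = bets(risk) − bets(conflict)`.

On the imaging side, the main GLM has four condition dummies, four
uncertainty-level modulators (mean-centered per run), and a response-time
covariate, all convolved with a double-gamma HRF, fitted to percent-signal-
change voxel series with one AR(1) prewhitening pass. Group maps are
voxelwise random-effects tests; candidate regions found in one matched half
of the cohort must replicate (same sign, one-sided α = 0.05) on the held-out
half, with cross-specificity checks against the other condition's level and
attitude.

## Worked example

```python
import ambicon as ac

gambles = ac.generate_gamble_set(seed=0)
session = ac.build_session(gambles, seed=0, n_runs=4, volumes_per_run=120)

true = ac.SubjectParameters(theta=1.0, gamma_a=0.8, gamma_c=2.0)
choices = ac.simulate_choices(true, session, seed=7)
fit = ac.fit_subject(choices, seed=0)
print(fit.params.gamma_a, fit.params.gamma_c)
print(ac.model_free_attitudes(choices))
```

prints (from `examples/02_fit_choices.py`):

```
true   : theta=1.00 gamma_A=0.80 gamma_C=2.00
fitted : theta=1.05 gamma_A=0.70 gamma_C=2.06  (NLL 88.0, 128 trials)
model-free attitudes: RA=0 AA=-6 CA=7
```

The fitted weights land near the generating ones after 128 trials; the
positive `CA` and `γ_C > 1` both read as conflict aversion, the negative `AA`
and `γ_A < 1` as ambiguity seeking. The `examples/` directory has one short
script per capability: task design, single-subject fitting, group behavioral
statistics, GLM amplitude recovery, and the full split-half ROI confirmation.

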