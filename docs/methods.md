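# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Task design

A deck always holds 100 cards; `type1_count = 100 − L` where the level `L`
ranges over 30 distinct even values including 6 and 94. The supplementary
list of the 30 levels is not public, so the default list is constructed to
satisfy every stated constraint simultaneously: 20 even levels ≤ 66
({6, 8, 12, 16, 20, 24, 28, 32, 36, 40, 44, 46, 50, 52, 56, 58, 60, 62, 64,
66}) and 10 even levels > 66 ({68, 72, 76, 78, 82, 84, 88, 90, 92, 94}).
Betting on a Type-2/3 card is the risk-neutral optimum exactly when
`10·L/200` beats both the $3 sure gain and the Type-1 bet, i.e. `L > 200/3`;
the ten levels above 66 deliver the benchmark of ten risk-neutral bets, and
the two seeded repeats (shared across conditions to keep the trial-level EV
match) are drawn from the ≤ 66 subset so the count stays ten over 32 trials.

Conflict messages are `(round(L/3), L − round(L/3))` and its swap: this
reproduces the (2, 4)/(4, 2) example at `L = 6`, disagrees with the even
split at every level, and keeps the message mean at `L/2` so the
information-neutral winning probability is `L/200` in all conditions.
Whether the original message asymmetry varied with level is unknown; a fixed
rule keeps the design deterministic.

Sessions hold 8 trials of each of the five trial types per run (gambles
6.5 s + ≥ 1 s fixation; fixation-only trials 7.5 s). At 200 volumes × TR
2.5 s a run has 200 s of slack beyond the 40 × 7.5 s trials; the slack is
distributed as seeded 0.5 s baseline gaps after trials, since the original
gap placement (an efficiency-optimized pseudorandom schedule) is not
recoverable. A 120-volume run is the zero-slack desk-scale variant used for
simulation-heavy work.

## Choice model

`W_j = x_j^θ π_j^γ` with `U_j ≡ W_j` — no extra temperature parameter; θ
already scales the weights and an additional inverse temperature would not be
separately identifiable here. γ applies only to options whose probability is
genuinely uncertain: the sure gain (π = 1) and the Type-1 bet (known count)
always use γ = 1, which is the only reading under which risk trials with
γ = 1 emerge as the stated special case. π for the uncertain options is the
information-neutral point estimate `L/200` (ambiguity-interval midpoint;
conflict-message mean), making the expected-value match literal.

"Second-order variance" is interpreted as the variance of the Type-2 winning
probability implied by the information state: 0 under risk, uniform-count
variance `L(L+2)/120000` under ambiguity, the two-point message variance
under conflict. Single-draw $0/$10 outcome variance cannot be the intended
quantity because it is identical across conditions whenever the marginal
means match; under this reading ambiguity > conflict at every level, which
is the stated ordering.

## Fitting

Per-subject maximum likelihood over `(ln θ, ln γ_A, ln γ_C, ln γ_I)` with
bounds θ ∈ [0.05, 5], γ ∈ [0.05, 10], L-BFGS-B from 5 seeded starts
(neutral point plus 4 random draws). The log parameterization matches the
log-normal attitude distributions and makes positivity structural. Trials
with no recorded response are dropped. A subject who always chose the sure
gain is flagged unidentifiable and left at neutral defaults. An exhaustive
grid search over the same objective is kept as an independent oracle; the
optimizer must never return a worse likelihood than any grid point. The
original estimation was likely Bayesian (the supplementary details are
unavailable); per-subject MLE is the reproducible choice and recovers the
generating parameters with r ≈ 0.93–0.96 at 128 trials.

## Group behavioral statistics

Outliers are flagged in a single pass: |x − mean| > 3 SD with the candidate
included (no iteration, no leave-one-out — the simplest reading of the rule),
on the AA and CA scores; flagged subjects leave all analyses. Effect sizes
use the printed convention d = t/√n, which reproduces all eight printed
(t, d) pairs to their printed precision. Ambiguity attitudes are log-normal
across subjects, so γ_A is tested and correlated on the log scale (ln γ_A vs
0); γ_C is tested against 1 on the raw scale — the combination that matches
the printed group statistics arithmetically. All p-values are two-sided,
α = 0.05.

## Synthetic data generator

**Population.** 32 subjects, half male, age ~ N(25.2, 5.6²) truncated at 18.
γ_A and γ_C are log-normal with arithmetic means 0.85 and 1.69; their SDs
(1.10 and 0.88) are the printed standard errors × √30 — the only defensible
scale available. θ is log-normal with median 1 and log-SD 0.3 (unreported;
a free choice documented here). γ_I shares the γ_A distribution as a
placeholder, since its behavioral findings are out of scope.

**Choices and RTs.** Choices are drawn trial-by-trial from the model's own
probabilities. ln RT = ln(condition median) + subject offset (SD 0.15) +
subject-by-condition offset (SD 0.12) + trial noise (SD 0.25), with medians
1.80 / 2.00 / 2.08 / 2.00 s for risk / ambiguity / conflict / ignorance and a
6.4 s cap (the response window is 6.5 s). These values were chosen so that
the paired risk-vs-conflict effect is large and negative and risk-vs-
ambiguity moderate and negative, the qualitative ordering the RT analysis
expects; no claim is made that the magnitudes replicate real data.

**BOLD.** Per subject and run, signal = Σ planted regions (subject amplitude
× the region's own convolved, mean-centered design regressor), added to every
voxel of a sphere; noise is temporally AR(1) (ρ = 0.3, stationary SD 1.5 in
PSC units) and spatially smoothed (Gaussian σ = 1 voxel, which leaves the
lag-1 coefficient untouched — the smoothing is spatial only). Output rides
on a baseline of 1000 so the analysis side must do its own PSC conversion.
Post-smoothing voxel noise SD is ≈ 0.27 PSC, chosen so that the weakest
planted effect (0.002 PSC/card) reaches a group-level t ≈ 5 at n = 16 —
calibration that makes the confirmation power check meaningful rather than
vacuous. Amplitude units are "PSC per regressor unit" where the regressor is
the HRF-convolved boxcar carrying the time-integral of the kernel; planted
and recovered values are always compared in these same units.

Attitude-coupled regions draw subject amplitudes as
`mean + SD·(ρ·z(attitude) + √(1−ρ²)·ε)` with targets ρ = +0.61 (region
loading on the ambiguity dummy, coupled to ln γ_A) and ρ = −0.67 (conflict
dummy, coupled to γ_C). Cross-loadings of every planted region are exactly
zero: the expected cross-check outcome is "no effect", and planting the
nonsignificant nuisance values the original table prints would make the
cross-checks systematically significant at this SNR.

**What the generator does not emulate:** anatomy, physiological noise,
motion, scanner drift, spatial heterogeneity of the HRF, and any mismatch
between the analysis design matrix and the true hemodynamics (the generator
uses the model's own regressors). Passing recovery tests therefore validate
the statistical machinery — not robustness to model misspecification.

## GLM

Canonical double-gamma HRF (shapes 6 and 16, unit scales, undershoot ratio
1/6), peak-normalized; convolution on a 0.1 s grid sampled at volume times.
"Mean-centered for each scan" is read as per-run centering of the level and
RT modulator values before convolution; the convolved parametric columns are
additionally demeaned within run, which removes the small residual mean left
by truncation at the run boundary and is absorbed entirely by the per-run
intercepts. The RT regressor is an onset impulse with amplitude equal to the
trial RT. Note the condition dummies dip slightly negative between trials —
the HRF undershoot — so "boxcar" describes the pre-convolution shape.

Fitting is OLS; with `ar1=True` (the pipeline default, since the synthetic
noise is AR(1) and unpreprocessed) one Cochrane–Orcutt pass estimates the
pooled lag-1 residual autocorrelation, quasi-differences both sides within
runs, and refits. Group maps: one-sample t (random effects), voxelwise
Pearson correlation with behavioral scores, paired-t contrasts, and a
minimum-statistic conjunction (both effects pass α with the same sign). The
Monte-Carlo cluster threshold simulates smoothed Gaussian maps, thresholds
two-sided at the voxel p, and returns the smallest extent whose family-wise
exceedance rate is ≤ 0.05.

## Split-half confirmation

Subjects are standardized on age, ln γ_A and γ_C, paired greedily by nearest
neighbour within sex (the matching algorithm is this package's construction;
none was specified), and one member of each pair goes to each group at
random. Exploration runs only on group 1: t-maps of the A-level and C-level
PEs thresholded at voxel p < 0.005, and attitude correlation maps thresholded
at p < 0.05 — the looser threshold reflects that a correlation of 0.6 at
n = 16 sits near the 0.005 critical value, so exploration at 0.005 would be
blind to plausible couplings. Local maxima are pruned to ≥ 4 voxels apart
and capped at 12 candidates per map (the scale of candidate counts the
procedure is meant to winnow). Spheres default to radius 3 voxels on the
desk-scale grid; the described radius of 10 "voxels" is kept configurable,
with the caveat that 10 voxels at 3.5 mm (35 mm) is anatomically implausible
and 10 mm may have been intended.

Confirmation averages the held-out group's raw time course over the sphere,
converts to PSC, refits the main model per subject, and tests the target
effect one-sided in the exploratory direction at α = 0.05 — "the same
result" read as sign consistency. Cross-checks (the other condition's level
PE; the other attitude coupling) are two-sided. Pooled whole-cohort
statistics are also reported for each ROI, mirroring the pooled follow-up
analyses. No subject ever contributes to both stages (asserted at runtime).

Calibration facts established by the suite: under pure noise the
per-candidate confirmation rate is ≤ α across 1000 replicate splits, and a
candidate whose effect lives only in the exploratory subjects is rejected
out-of-sample at ≈ α. Power facts: the planted −0.015 and +0.002 PSC/card
regions are confirmed with the correct signs at study scale. For the
attitude-coupled regions, the sampling SD of a correlation at n = 16
(≈ 0.16 in Fisher units around ρ = 0.61) makes joint exploratory-plus-
confirmatory success intrinsically probabilistic (~50–75% per dataset), so
the deterministic checks are sign-correctness of the candidates and the
pooled n = 32 correlation landing in the Fisher 95% CI of the target;
the split-half confirmation flags for these regions are reported as
outcomes, not guarantees.

## Problem sizes

Simulation-heavy checks run at desk scale by choice: 16³ or 10³ voxel grids
instead of a 64×64×38 acquisition matrix, 120-volume runs, 2 runs for
single-subject recovery work, the full 4 runs wherever choices feed fitting
(128 trials is the study's behavioral size), 200 subjects × 128 trials for
recovery, 50 replicate datasets for amplitude CIs, and 150–200 noise
datasets × 5 matched splits for null calibration. The statistics being
checked (calibration rates, recovery bias, CI coverage) do not depend on the
grid being brain-sized.

## Known limitations

- The exact 30-level list, the original estimation procedure, the
  exploratory threshold, and the slack placement in the schedule are
  reconstructed from constraints, not copied; group-level numbers from the
  original participants are not reproducible from synthetic data and are not
  targets.
- One prewhitening pass with a single pooled ρ; no spatial noise model
  beyond isotropic smoothing. An optional DCT high-pass (default cutoff
  3 cycles per run) is provided but applied nowhere by default, since the
  generator injects no drift and the original filter's exact form is
  unstated.
- `γ_I` (ignorance) is carried through fitting and the GLM for structural
  completeness but its scientific content is out of scope.
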