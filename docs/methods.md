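# Methods

This note documents the models, estimation procedures, numerical choices and
limitations of `mcdmeg`, in the spirit of a statistical-software methods
appendix.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Detector model

The Multisensory Correlation Detector treats the audiovisual correspondence
problem like visual motion detection: two input lines, a set of low-pass
filters, and two multiplicative subunits whose product codes temporal
correlation and whose difference codes lag.  Filters are exponential kernels
`f(t) = t·exp(−t/τ)` with modality time constants `τ_A`, `τ_V` and a shared
audiovisual constant `τ_AV` (all in milliseconds; the kernel peaks at
`t = τ`).  The subunit algebra is implemented exactly as written in the
model definition; no kernel normalisation is applied, but discrete
convolutions are scaled by `1/rate` so summaries are invariant to the
simulation rate.

**Simulation grid.** Default 1 kHz.  Stimulus events have 10 ms physical
granularity, and the test suite verifies that time-averaged outputs at 1 kHz
agree with a 10 kHz dense-grid oracle within 1% of the typical summary
magnitude.  Kernels are truncated at 10 τ (residual mass < 5·10⁻⁴ of the
total; the tail value is 10·e⁻⁹ of the peak).

**Input encoding.** The model's input encoding is a modelling choice, not
part of the model definition; the default is a unit-mass rectangular pulse
of 10 ms per event — the physical duration of the noise bursts and flashes —
with a single-sample delta available by option.  Changing the encoding
rescales outputs but barely moves the z-scores used downstream.

**Summaries.** `MCD_CORR` and `MCD_LAG` are averaged over a half-open 3-s
window starting at the first impulse (three times the sequence duration;
at rate `r` the window holds exactly `3r` samples), then z-scored across the
stimulus set with the population-SD convention, per participant when time
constants differ per participant.  Z-scoring a constant set raises a
degenerate-input error rather than returning NaNs.

**Sign convention.** `MCD_LAG = −S1 + S2` makes a vision-leading impulse
pair yield a positive time-averaged lag; this is asserted against the dense
oracle in the tests, not assumed.  A positive behavioral slope on `MCD_LAG`
therefore corresponds to more "vision first" reports.  A by-product of the
asymmetric filters (τ_V > τ_A at the fitted values) is a negative lag at
physical synchrony — vision must physically lead to be perceived as leading.

## 2. Stimulus design

Candidate sequences carry 5 events per modality, uniformly distributed over
[0, duration − pulse) with a 20 ms within-modality minimum gap enforced by
rejection sampling (two 10 ms pulses may not overlap).  Each candidate is
scored with a packaged mean-observer preset (the across-participant mean of
the fitted time constants: τ_A ≈ 68.9, τ_V ≈ 125.7, τ_AV = 746 ms);
scoring parameters are configurable.

"Large range with decorrelated outputs" is operationalised as: maximise
`range(corr_avg) × range(lag_avg)` over the selected set subject to
`|Pearson ρ(corr_avg, lag_avg)| < 0.2`.  Pools small enough for exhaustive
subset enumeration are solved exactly (the tests compare against a
brute-force oracle); larger pools use greedy seeding from summary-space
extremes plus local single-element swaps under a fixed evaluation budget.
Because the objective pushes the spread while the constraint caps the
correlation, selected sets often sit near (below) the 0.2 boundary.

The original experiment's six sequences are not redistributed here; the
packaged default set is a synthetic stand-in selected from a 10⁴-candidate
pool with a fixed seed by this same procedure.

## 3. Behavioral model and joint fit

Responses ("same cause" / "vision first", coded 1) follow a mixed-effects
logistic model per task: `logit P = β0_task + β1_task · z + b_p` with
`b_p ~ N(0, σ_task²)` a participant random intercept, and `z` the z-scored
`MCD_CORR` (causality) or `MCD_LAG` (temporal order) of the presented
stimulus.  Seven fixed parameters are fitted jointly: the three time
constants (shared across tasks through the z-scores) and an intercept and
slope per task.  The intercept/slope are task-dependent; only this reading
yields the seven-parameter count.  Random-effects structure is
intercept-only; σ is estimated per task as a nuisance parameter.

**Marginal likelihood.** Random intercepts are integrated out by adaptive
Gauss–Hermite quadrature (15 nodes): a Newton search locates each
participant's posterior mode, and nodes are recentred there and scaled by
the posterior curvature.  Plain (non-adaptive) quadrature was tried first
and missed a dense-integration oracle by ~10⁻² at σ ≈ 1.2 because the
posterior is narrow and offset with hundreds of trials per participant; the
adaptive scheme reaches < 10⁻⁶ and is cheaper.  Trials enter as exchangeable
Bernoulli draws (no binomial coefficient), so the null model's NLL is
exactly `n_trials · ln 2`.  Numerical guards: linear predictors are clipped
at ±700 before exponentiation, and σ is capped at 10³ logits (beyond which
the prior is indistinguishable from flat) so the Newton step stays finite
when the outer optimiser overshoots.

**Optimisation.** The outer search runs over log time constants in
[20, 3000] ms with the four link parameters and two σ profiled out by an
inner warm-started quasi-Newton fit; a small in-package particle swarm
(no PSO implementation exists in the installed scientific stack) explores
the box and a Nelder–Mead simplex refines the best particle.  The whole
procedure restarts from fresh swarms (default 10) keeping the best
likelihood; everything is deterministic given the seed.

**Goodness of fit.** Pseudo-R² is defined as the squared Pearson correlation
between predicted and observed per-stimulus response proportions, per
participant and task, with the participant's posterior-mode intercept
included in the prediction; zero-variance observations are flagged rather
than silently scored.  Task comparison is a paired t-test across
participants (degenerate zero-variance differences are flagged with an
infinite statistic and NaN p).

**Monte-Carlo power.** Datasets are simulated at the study design (13
participants × 6 stimuli × 75 trials per task), with the fixed-effect slope
set to the observed effect size, intercept 0, and random-intercept SD 1
logit (the generator condition adopted for the between-participant spread;
the source analysis does not report its random-effect variance).  Each
dataset is refitted and the slope tested by a two-sided Wald z-test at
α = 0.05; power is the significant fraction with a Clopper–Pearson exact
binomial 95% CI.  Note an exact lower bound of 99.63% (99.80%) requires at
least 996 (1843) all-significant simulations, which fixes the simulation
counts used by the acceptance script (1000 and 1850).  The Wald test
degenerates under complete separation (Hauck–Donner); the saturation tests
therefore use large-but-non-separating slopes.

## 4. Evoked pipeline

Epochs span [−200, 1800) ms around the first event at 250 Hz — half-open by
convention, hence exactly 500 samples.  Artifact rejection keeps a trial iff
its peak-to-peak range over all sensors is at most the threshold (default
2·10⁻¹¹ T for magnetometer-like channels; the planar-gradient figure is
interpreted as 9·10⁻⁹ T/cm and is config-overridable).  Sensor triplets are
merged by a configurable weighted sum (unit weights by default); the
vendor-specific field transformation behind real triplet merging requires
proprietary sensor geometry, so synthetic layouts are generated directly at
the merged channel count.  Band-pass (1–40 Hz) and decimation helpers are
provided but are pass-throughs for the band-limited synthetic data.

Unisensory removal regresses, per sensor, the task evoked response on the
auditory and visual localizer evoked responses pooled across all time points
and stimuli (the pooled reading of the ambiguous per-stimulus alternative),
and subtracts the weighted sum.  The operation is idempotent; near-collinear
regressors raise a warning carrying per-sensor condition numbers.  Cluster
RMS is the root mean square over a sensor × time mask.  Brain–behavior
statistics: a linear mixed model (participant random intercept) of cluster
RMS on the z-scored summaries with a task-interaction test, and a
single-trial mixed logistic model comparison (null / activity /
activity+task / activity×task) by likelihood-ratio tests with an AIC
tie-break, reporting per-task simple effects; perfect separation is detected
from a diverging slope and flagged.

## 5. Cluster permutation inference

The statistic map is the elementwise paired t over participant × stimulus
pairs (78 pairs → 77 degrees of freedom at full scale).  Samples with
|t| > 2.6 — the two-sided critical value at p = 0.01 for df = 77 — are
grouped into connected components under sensor adjacency plus
consecutive-time connectivity, positive and negative clusters separately;
cluster mass is the sum of member t-values.  The null distribution is the
maximum |mass| over both polarities under within-pair condition flips
(sign flips of paired differences), preserving the participant/stimulus
structure; `p = (1 + #{null ≥ observed}) / (1 + n_perm)` with 10⁴ draws by
default, or exact enumeration of all 2ⁿ patterns for ≤ 12 pairs.  A
spatial-only variant tests per-sensor score maps against zero with
participant-level sign flips.  Adjacency is a plain symmetric boolean
matrix (synthetic layouts use 8-neighbour grids; real layouts load from an
edge-list CSV); no covariance weighting enters the cluster definition.  The
implementation is cross-checked in the tests against exhaustive enumeration
at 3 pairs, a flood-fill component oracle, a ≤ 2% empirical false-positive
criterion on null data, and the independent MNE implementation.

## 6. Model-based TRF encoding

Each sensor is a lagged linear model of the four detector component time
courses.  The design matrix holds zero-padded shifted copies of each
component (columns ordered component-major); per-sensor ridge solutions
share one Gram matrix.  The lag window is a free choice (the source analysis
does not report one); the default is causal 0–500 ms, spanning typical
evoked-response latencies, with the synthetic ground truth using 0–300 ms.
Predictors are standardised with training-fold statistics only.  The ridge
penalty is either fixed or selected by nested leave-one-fold-out search over
a logarithmic grid (10⁻²…10⁴) before the test fold is touched; at
single-trial SNR 5 the nested policy lands in the regime where true-filter
recovery exceeds r = 0.9, while a near-zero penalty does not.

Scoring is leave-one-(participant, stimulus)-out: 13 × 6 = 78 folds at full
scale.  Per fold and sensor, the Pearson ρ between prediction and held-out
data is computed for each component separately with all other components'
weights zeroed (the full model is fitted once; attribution zeroes weights at
prediction time).  ρ is defined as 0, with a flag, when a prediction is
constant.  Early/late scoring windows (default split at 500 ms) reuse the
same fits and only restrict the correlation window.  When two predictors are
strongly correlated, their attributions overlap — the tests demonstrate this
with a duplicated predictor, where ridge provably splits the weight evenly;
attribution specificity claims are therefore only meaningful for weakly
correlated components.

## 7. Synthetic data generator

The generator emulates the study conditions: 13 participants; per
participant 2 tasks × 3 blocks × 25 repetitions of 6 sequences plus 2 + 2
passive unisensory localizer blocks of 25 × 6 — 1500 trials, 75
presentations per stimulus per task; stimulus order pseudo-random with no
more than 3 consecutive repeats (enforced across block boundaries).
Observers use the fitted per-participant time constants (packaged table) and
task slopes 1.80 (causality) and 1.02 (temporal order), intercept 0,
random-intercept SD 1.  Epochs are built as
`Σ_i TRF_true(n,i,·) ∗ MCD_i(t) + β_A(n)·aud(n,t) + β_V(n)·vis(n,t) + noise`,
where the ground-truth TRFs are damped oscillations (random frequency 3–8 Hz,
decay 50–150 ms) on component-specific sensor patches so attribution has a
known spatial answer, unisensory responses are event trains convolved with
fixed per-modality damped-oscillation kernels with per-sensor topographies,
and localizer epochs contain only their modality's term.  Noise is white
Gaussian (1/f optional) scaled so the dataset-wide signal/noise variance
ratio equals the target SNR (default 5).

What the generator does **not** emulate: realistic MEG noise spectra and
spatial covariance, leadfield-based sensor topographies, eye/cardiac
artifacts, head movement, learning or lapses in the observer, and
reaction-time structure.  Passing tests therefore validate the statistical
machinery and its calibration under the stated generative assumptions — not
the neuroscientific conclusions on real recordings.

## 8. Problem sizes

Full-scale quantities (10⁶-candidate pools, 10⁴ permutations, 102-sensor
epochs, 10 restarts) are parameters, with package defaults chosen for
single-CPU desk scale: stimulus pools of 10⁴ for the packaged set and the
acceptance script, 1000/1850 power simulations (the smallest counts whose
exact-binomial bounds can reach the reported values), parameter recovery
averaged over 2 seeds with 4 restarts, cluster false-positive calibration
over 200 null runs of 5 × 8 maps with 199 permutations, and TRF validation
on 12–24-sensor grids.  The end-to-end pipeline default is 4 participants ×
5 repetitions × 24 sensors.

## 9. Known limitations

- The joint fit recovers `τ_A` and `τ_V` well at study-scale trial counts
  but `τ_AV` only weakly (the lag z-scores constrain it loosely); recovered
  auditory constants show a mild downward finite-sample bias within the
  documented tolerance.
- Wald-based significance in the power analysis understates evidence under
  near-separation; at the study's effect sizes this regime is not reached.
- The spread objective for stimulus selection is one reasonable reading of
  "a large range of responses"; other objectives (e.g. determinant-based
  spread) would select different sets with similar decorrelation.
- Single-trial brain–behavior model comparison assumes a common activity
  scaling across participants (activity is globally z-scored).
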