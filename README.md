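# mcdmeg

Analysis pipeline for studying how the brain decides whether auditory and
visual event streams belong together (causal inference) and which modality
came first (temporal order), built around the **Multisensory Correlation
Detector (MCD)** — a Hassenstein–Reichardt-style circuit adapted to the
audiovisual correspondence problem — and a **model-based temporal response
function (TRF)** approach that asks how much of multichannel neural activity
the model's internal dynamics can explain.

The package is aimed at researchers in multisensory perception and neural
encoding models.  Every stage runs end to end on synthetic data with known
ground truth, so the statistical machinery can be validated without any
recording hardware or data download; real datasets in the same tabular /
epoch formats can be substituted path-for-path.

## The model

Auditory and visual impulse trains `S_A(t)`, `S_V(t)` are low-pass filtered
with exponential kernels

```
f_mod(t) = t · exp(−t / τ_mod),            mod ∈ {A, V, AV}
MCD_A = f_A ∗ S_A,    MCD_V = f_V ∗ S_V
```

and combined by two mirror-symmetric subunits, each delaying one modality
through the shared audiovisual filter before multiplying:

```
MCD_S1 = (MCD_A ∗ f_AV) · MCD_V
MCD_S2 = (MCD_V ∗ f_AV) · MCD_A
MCD_CORR = MCD_S1 · MCD_S2          (correlation strength)
MCD_LAG  = −MCD_S1 + MCD_S2         (sign and size of the lag)
```

Time-averaged over a 3-s window from the first impulse and z-scored across a
stimulus set, `MCD_CORR` predicts "same cause" judgments and `MCD_LAG`
predicts "vision first" judgments through a mixed-effects logistic model
with participant random intercepts.  For neural data, each sensor is
modelled as a lagged linear convolution of the four component time courses
(`MCD_A`, `MCD_V`, `MCD_CORR`, `MCD_LAG`), estimated by ridge regression and
scored by cross-validated Pearson correlation
(`MEG(n,t) = Σ_i Σ_τ TRF(n,i,τ) · MCD_i(t−τ) + ε`).

## What is in the box

| module | contents |
| --- | --- |
| `mcd_core` | detector simulation, summaries, z-scoring, events-TSV I/O |
| `stimulus_design` | random sequence pools; selection of a set with decorrelated CORR/LAG |
| `behavior_fit` | adaptive Gauss–Hermite mixed logistic likelihood, joint 7-parameter fit (swarm + simplex), pseudo-R², Monte-Carlo power |
| `evoked_pipeline` | epoching, peak-to-peak rejection, sensor-triplet merge, unisensory removal, cluster RMS, brain–behavior regressions |
| `cluster_stats` | spatio-temporal cluster formation and sign-flip permutation inference |
| `trf_encoding` | lagged ridge TRFs, leave-one-(participant, stimulus)-out scoring, per-component attribution |
| `synthetic_data` | trial designs, logistic observers, TRF-convolved sensor epochs with known ground truth |
| `pipeline` / `cli` | YAML-configured end-to-end runner (`mcd run-all`) with a reproducibility manifest |

## Worked example

Score three one-second 5-click/5-flash sequences with the fitted
participant-1 time constants (τ_A = 84 ms, τ_V = 130 ms, τ_AV = 519 ms):

```python
from mcdmeg import EventSequence, MCDParams, encode_events, mcd_respond, summarize

params = MCDParams(tau_a=84, tau_v=130, tau_av=519)
seqs = {
    "synchronous":         EventSequence((0.1,0.3,0.5,0.7,0.9), (0.1,0.3,0.5,0.7,0.9)),
    "vision leads 100 ms": EventSequence((0.2,0.4,0.6,0.8,0.99), (0.1,0.3,0.5,0.7,0.89)),
    "uncorrelated":        EventSequence((0.05,0.12,0.55,0.6,0.95), (0.3,0.42,0.47,0.75,0.8)),
}
for name, seq in seqs.items():
    s_a, s_v = encode_events(seq)
    s = summarize(mcd_respond(s_a, s_v, params, first_onset=seq.first_onset))
    print(f"{name:22s} corr_avg = {s.corr_avg:.3e}   lag_avg = {s.lag_avg:+.3e}")
```

prints

```
synchronous            corr_avg = 1.650e-08   lag_avg = -2.400e-05
vision leads 100 ms    corr_avg = 1.688e-08   lag_avg = +3.578e-06
uncorrelated           corr_avg = 1.473e-08   lag_avg = -4.982e-05
```

Reading the numbers: temporally correlated sequences (the first two) yield a
higher time-averaged `MCD_CORR` than the uncorrelated one, so an observer is
more likely to report a common cause for them.  `MCD_LAG` moves positive
when vision leads; note the negative value at physical synchrony — with a
slower visual than auditory filter (130 vs 84 ms) the model reproduces the
classic finding that vision must physically lead to be perceived as leading.
Raw magnitudes are arbitrary (they scale with input gain to the fourth and
second power); all downstream modelling uses the z-scores across a stimulus
set.

Run the full synthetic pipeline (stimulus design → observer simulation →
behavior fit → evoked cluster contrast → TRF encoding) from the shell:

```bash
mcd run-all --seed 1 --out results_demo
```

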