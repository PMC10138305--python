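# Methods

## Problem setting

The package classifies 20 s windows of multichannel physiological recordings
(ECG, electrodermal activity, respiratory effort; 1250 Hz) from preschool-age
children into *children who stutter* (CWS) vs. *children who do not stutter*
(CWNS) while they speak, and explains the decisions. Supervision is weak:
only the window-level group label is known, while the class-indicative
physiological patterns are sparse (2–5 s), appear at unknown timestamps,
asynchronously across modalities, and not in every modality. This is a
multiple instance learning (MIL) problem: a window is a *bag* of nineteen 2 s
*instances* (1 s overlap), the instance labels are never observed, and the
bag label follows the MIL assumption Y = max_i y_i.

Label convention throughout: CWS = 1 is the positive class for all metrics
(precision, recall, specificity). The classical MIL literature would call the
CWS bag "negative" (a bag whose witnesses all share one class); we keep
semantic labels and document the mapping here once.

## Preprocessing

* Zero-phase Butterworth high-pass filter (default cutoff 0.05 Hz, order 2,
  forward–backward via second-order sections) removes DC and baseline drift
  from every channel. Because the filter is applied once over the whole
  recording, any constant per-subject offset in a channel's *amplitude* is
  removed; subject-level differences survive in rate-derived descriptors
  (heart rate, breathing rate) and in variability.
* Session windows: 20 s with 15 s hop (5 s overlap) inside each condition
  span; a span of T seconds yields floor((T−20)/15)+1 windows.
* Scripted-task windows are anchored on picture onsets t_p: window 1 covers
  [t_p−13, t_p+7) (onset at time-step 13), window 2 covers [t_p+5, t_p+25)
  (speaking). Both anchorings are configurable; coordinates are half-open,
  0-based seconds.
* Each window is segmented into 19 ordered 2 s segments with 1 s hop.

## Features

Low-level descriptors (LLDs), one value per 0.8 ms tick (1250 Hz):

* **HR** — instantaneous heart rate from ECG R-peaks (band-pass 5–30 Hz,
  threshold mean+2·std, 250 ms refractory period), sample-and-hold at
  60/RR between successive peaks. The detector is deliberately simple and
  pluggable; it is adequate for clean and synthetic ECG.
* **EDA** — the filtered channel itself.
* **RSP-rate / RSP-amp** — breaths/min from successive breath-peak intervals
  and peak-to-trough amplitude of the enclosing breath, both sample-and-hold.
  LLDs are derived once over the whole recording so that beats and breaths
  straddling window edges are seen with context.

High-level descriptors (HLDs): min, max, std, var, mean, median of each LLD
over each 2 s segment. Variance and std use the population convention
(divide by n); segments fully enumerate their samples and the convention
makes var = std² exact. A raw bag is four 19×6 matrices (19×24 = 456 cells
flattened, modality-major EDA, HR, RSP-amp, RSP-rate; functional-minor in
the order above).

Change-scores: per participant, the *baseline-score* Y_b of a modality is
the mean 6-dim HLD vector over all baseline-condition segments. Each task
segment's *post-score* Y_t is compared with Y_b by Euclidean distance and
cosine similarity (kept as a similarity; larger = more alike), giving four
19×2 matrices (152 cells). Vectors are compared in raw units without
modality-specific normalization; a zero-norm vector yields cosine 0 with a
warning. Change-scores express a child's response relative to their own
neutral state and therefore discard stable inter-individual offsets.

## The MI-MIL model

Per modality m, an embedding MLP (depth 2, ReLU between layers, linear
output, width 32) maps each instance to p = 32 dims. A modality-specific
self-attention pooling computes a_im = softmax_i(w_mᵀ tanh(V_m e_im)) with
L = 16, and the bag embedding t_m = Σ_i a_im e_im; the weights are
non-negative, sum to one, and contain no positional term, so the pooled
representation is invariant to instance order. The four bag embeddings are
concatenated into X ∈ R^128 and fused by a non-local embedded-Gaussian
operator: treating each scalar dimension as a position,
z_i = Σ_j softmax_j(θ(x_i)ᵀφ(x_j)) · g(x_j) with position-wise linear maps
θ, φ, g (1×1 convolutions over positions; with one input channel these
reduce to scalar weights, so the pairwise similarity is exp(c·x_i·x_j)).
There is no residual connection. A two-layer classifier head with sigmoid
produces p(CWS).

The network is plain numpy (float64) with hand-derived gradients; the
backward pass is verified against central finite differences in the test
suite, and the vectorized pooling and fusion are verified against
explicit-loop reference implementations to 1e-10.

Training: Adam (lr 3e-4), bag-level binary cross-entropy, batch 32, up to
120 epochs with early stopping and model selection on validation F1
(patience 20), three random restarts per seed with the best-validation
restart kept (no test information enters model selection). Instance
features are standardized per modality and per column with train-set
statistics stored in the model. Runs are fully deterministic per seed;
reported metrics average three training seeds {0, 1, 2}. The learning-rate
and size defaults were fixed by a small grid search on a synthetic
validation cohort generated with a seed disjoint from any evaluation
cohort.

Evaluation protocol: person-disjoint hold-out — 3 CWS + 3 CWNS participants
in test, 3+3 in validation, remainder in training; every window follows its
participant. All three compared models (MI-MIL, attention-MIL, flat
supervised) are trained under the identical protocol: gradients on the
training set, early stopping, restarts and model selection on the
validation set. Because a 3+3-participant test draw is highly contingent,
the study runner gives each training seed its own split (all model kinds
share every split, keeping the comparison paired) and averages over seeds.

Baselines: *attention-MIL* concatenates all modalities' features per
instance into a single stream with one embedding block and one attention
pooling (no fusion) — with a single modality it is architecturally identical
to MI-MIL without fusion, which the tests exploit as an ablation check.
The *flat supervised* baseline is a two-hidden-layer MLP (64, 32) on the
flattened 19×24 grid (scikit-learn), representing position-specific
supervised learning without the MIL structure.

Ridge feature ranking: windows averaged over segments to one 24-vector,
standardized, ridge regression (α = 1) against the labels, features ranked
by signed coefficient.

## Synthetic cohorts

The generator produces the statistical structure of the study, not
physiological morphology:

* **Backgrounds.** ECG is a spike train whose beat times integrate an
  instantaneous rate (per-subject mean 100 ± 8 bpm); respiratory effort is a
  sinusoid with per-subject rate 25 ± 3 breaths/min and slowly wandering
  amplitude; EDA is a tonic level (5 ± 1.5 µS) plus slow wander and sensor
  noise. Slow wander uses smoothed noise with 20–40 s correlation.
* **Spontaneous activity.** Every child, in both groups and both conditions,
  produces class-neutral transient events (NS-SCR-like EDA bumps, transient
  HR accelerations/decelerations, breathing-rate/depth excursions) at a few
  per minute with lognormal amplitudes. Stable per-subject *trait* lognormal
  multipliers scale each child's event rate and response magnitude —
  the labile/stabile individual-difference dimension familiar from
  electrodermal research. The magnitude trait scales spontaneous and
  class-indicative responses alike, so absolute response size is confounded
  with subject identity, and population-level aggregate statistics are a
  poor class cue — mirroring the study's motivation for baseline-referenced
  features and for weakly supervised pattern extraction.
* **Class patterns.** Each CWS task window receives, independently per
  modality with probability 0.6 (at least one modality always), a 2–5 s
  motif at a uniformly random onset: a smooth compact-support ramp bump in
  EDA, a biphasic freezing dip-then-rise in the instantaneous heart rate,
  and rate/depth elevations in respiration. Motif amplitudes default to 4
  per-modality effect units (eda 0.1 µS, hr 4 bpm, rsp-rate 2 breaths/min,
  rsp-amp 0.15 relative), scaled by the subject's magnitude trait, so a
  motif stands clear of the child's own spontaneous events (lognormal,
  median 1.2 units) while absolute amplitudes overlap across children. CWNS
  windows carry no class motifs (an optional distinct low-amplitude
  freezing-first motif is available but off by default). With amplitude 0
  the groups are statistically indistinguishable.
* **Ground truth.** Pattern onsets/durations per window and modality, plus
  instance labels marking overlapping segments, are emitted for testing
  only; they are never visible to training. Because adjacent windows overlap
  by 5 s, ground truth is recomputed from absolute onsets so neighbouring
  windows also list patterns that bleed into them.
* Sessions default to 240 s baseline plus 160 s task (free-speech style)
  with 20 subjects per group, so each child contributes ten 20 s task
  windows — the same order as a ten-trial picture-viewing protocol yields
  per child. The scripted style spaces 10 picture trials 40 s apart.
  Session lengths are the package's desk-scale choice of study condition;
  all sizes are configurable.
* All randomness flows from one master seed; per-subject streams are derived
  through fixed spawn keys, so a subject's data is invariant to cohort size.

What the generator does **not** emulate: realistic ECG/EDA/respiratory
morphology, motion artifacts, sensor dropout, speech acoustics, or any claim
about what CWS-distinctive patterns actually look like — the injected motifs
are test instruments whose shapes follow the qualitative descriptions the
classifier is meant to recover. Passing tests therefore demonstrate that the
pipeline recovers *planted* structure under realistic nuisance variation,
not that the physiology of stuttering is as simulated.

## Interpretation

KernelSHAP with grid cells (feature × timestep; 456 raw or 152 change-score
players) as coalition units. Missing cells are imputed by averaging the
model output over a background set — a medoid-style sample (KMeans centers
snapped to nearest real bags, k = 20) of training bags. Coalitions are
enumerated size-complete while the sample budget (default 4096) allows and
sampled with Shapley-kernel weights beyond that; the efficiency constraint
is enforced exactly by variable elimination, so the values sum to the
explained score minus the background expectation. With full enumeration the
estimator is exact, which the tests verify against exhaustive Shapley
enumeration on small grids. Budgets below twice the player count trigger a
widened-tolerance warning.

The explained scalar is 1 − p(CWS), the CWNS-side score: positive Shapley
values (blue) push toward CWNS, negative (red) toward CWS. Global importance
for a class is the mean personalized grid over correctly classified test
windows of that class. Heatmaps put features on X, the 19 timesteps on Y,
with a diverging blue/red map and symmetric limits at the 99th percentile of
|values|; personalized plots draw one feature's 19-step trajectory with each
segment shaded by its Shapley value (pass a shared limit to compare
participants).

## Numerical choices and degenerate inputs

* Softmaxes (attention, fusion) are max-stabilized; non-finite logits raise.
* HR/RSP event-detector failures fall back to a caller-supplied running
  value and warn; empty LLD series and wrong-duration windows raise.
* Windows whose span is too short yield an empty list with a warning;
  scripted onsets too close to the recording edge skip their pair.
* Recordings not at 1250 Hz are linearly resampled (warning above 1%
  mismatch).
* Single-class test sets leave recall or specificity undefined (NaN) with a
  warning; a training set with one class raises.

## Known limitations

* The fusion operator's capacity under the 1×1-convolution parameterization
  is a single pairwise-similarity scale and a single unary gain; it encodes
  dimension-pair relations but cannot re-mix channels. The ablation path
  (fusion off) is exposed for comparison.
* The R-peak and breath detectors are threshold-based and untested against
  ambulatory artifacts; real deployments should swap in a clinical-grade
  detector behind the same function surface.
* KernelSHAP at 456 players with the default budget of 4096 samples is a
  regularized regression estimate, not exact; only small grids are exact.
* Synthetic findings transfer to real cohorts only insofar as the nuisance
  model (trait heterogeneity, spontaneous activity, noise) spans the real
  variability.
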