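# Methods

`tdprisk` implements an in-silico pipeline for assessing the torsadogenic
(TdP) risk of drugs: in-vitro multi-channel dose–inhibition data are
summarised as uncertainty-quantified Hill-curve ensembles; each sampled
block set drives a paced human-ventricular myocyte simulation; per-beat
electrophysiological biomarkers are collected into beat-indexed
"variability series"; and a small 1-D convolutional network classifies a
series into high / intermediate / low TdP risk, evaluated by a repeated
one-sample-per-drug resampling test.

## Hill-curve uncertainty quantification

For one drug and channel, fractional block at concentration D follows the
Hill model

    block(D) = 1 / (1 + (IC50 / D)^h),

with block(0) = 0.  Measurements are modelled with independent Gaussian
residuals on the block fraction with an inferred noise scale σ.  Priors:
log-uniform IC50 over [1e-3, 1e6] nM, uniform h over (0, 10], log-uniform σ
over [1e-4, 1].  The posterior is sampled with an affine-invariant ensemble
(emcee, 16 walkers initialised in a tight ball around a coarse grid fit,
1,500 burn-in steps), and the post-burn-in chain is
thinned evenly to the requested sample count (2,000 per drug × channel in
the standard configuration).  Split-R̂ is computed per parameter and
reported on the result; values above 1.05 attach a warning but do not
raise, because near-noise-free data legitimately produce degenerate
within-chain variances.  With a fixed seed the sampler is bit-reproducible
(the seed fixes both walker initialisation and the proposal stream).

Block sets are expanded over the posterior × Cmax-multiplier grid (1–4 ×
Cmax by default; 2,000 × 4 = 8,000 sets per drug).  Channels without
measurements are treated as unblocked.

## The paced myocyte model

The cell-simulation module defines a pluggable model contract — named
conductance scale factors for {INa, INaL, ICaL, IKr, IKs, IK1, Ito}, a
stimulus, Vm/Cai accessors and readable current outputs — and ships a
reduced phenomenological human-ventricular action-potential model written
for speed and qualitative fidelity rather than biophysical completeness.
It has 8 state variables: Vm, gates (INa inactivation, INaL inactivation,
ICaL voltage-dependent inactivation, IKr activation, IKs activation, Ito
inactivation) and intracellular calcium.  Fast activation gates (INa m³,
ICaL d, Ito r) are treated as instantaneous steady-state functions of
voltage; IK1 is an instantaneous inward rectifier; a small sodium
background leak balances IK1 at rest; a phenomenological NCX readout is
exposed but excluded from the net-charge metric.  Calcium follows ICaL
influx with first-order decay (τ = 160 ms).

Conductances (mS/µF): gNa 6.0, gNaL 0.02, gCaL 0.08, gKr 0.06, gKs 0.016,
gK1 0.42, gto 0.03.  These were tuned once so that the control model paced
at cycle length 2,000 ms (30 bpm) shows: resting Vm ≈ −86 mV, peak ≈ +55 mV,
APD90 ≈ 260 ms, a calcium transient peaking near 2.4 × diastolic, and —
critically for the pipeline's probes — monotone responses to channel
block: 50% IKr block prolongs APD90 without repolarization failure, and
ICaL block reduces the inward-charge ratio qInward below 1.

Drug effects enter exclusively as conductance scaling g → g·(1 − block),
so two successive block applications compose multiplicatively in the
survival fractions.

Under hERG (IKr) block the model's APD90 lengthens smoothly up to roughly
20% block and then bifurcates into an EAD-like regime — greatly prolonged
or outright failed repolarization, eventually alternating beat-to-beat —
consistent with the known arrhythmogenic behaviour of strong hERG block at
bradycardic rates.  Duration biomarkers carry a "not repolarized" sentinel
for such beats.  The bifurcation point is a property of this reduced
model, not a calibrated threshold.

Integration is a deterministic fixed-step RK4 scheme (numba-compiled) with
phase-dependent substeps: 0.02 ms through the stimulus/upstroke (first
20 ms), 0.1 ms through plateau and repolarization (to 800 ms), 0.5 ms in
diastole; output is recorded on a uniform 1-ms grid, state carried across
beats without reset.  The model reaches its pacing limit cycle within ~5
beats (it has no slowly accumulating ion concentrations), so the standard
1,000-beat protocol is deeply in steady state and shorter runs (20–60
beats) are used in unit tests; the 1,000-beat protocol itself is exercised
in the acceptance checks.  A 1,000-beat run takes roughly half a minute on
one CPU.

## Biomarkers

Seven per-beat biomarkers:

* **qNet** — trapezoidal integral over one cycle of INaL + ICaL + IKr +
  IKs + IK1 + Ito (A/F·ms).
* **qInward** — ½·(AUC_ICaL,drug/AUC_ICaL,control +
  AUC_INaL,drug/AUC_INaL,control), integrating the signed (inward-negative)
  currents, so the ratio of two negative areas is positive and equals 1
  with no drug.  Drug and control beats are paired by beat index from two
  runs of the identical protocol; the control run is computed once per
  model configuration and reused.
* **APD50/APD90, CaD50/CaD90** — time from the upstroke (argmax of the
  first difference) to the first crossing of peak − fraction·(peak −
  baseline), crossing located by linear interpolation.  The baseline is the
  diastolic level around the stimulus: the lower of the first sample
  (pre-stimulus) and the mean of the final 10 ms of the beat.  Taking the
  minimum keeps the baseline diastolic when a beat fails to repolarize; in
  that case a "not repolarized" sentinel is set and the duration reported
  is the time from upstroke to beat end.
* **dVm/dt_max_repol** — the maximum first-difference quotient of Vm inside
  the window between the APD30 and APD90 crossings (window bounds
  configurable).  The signed convention is kept: normal monotone
  repolarization gives negative values; positive values flag EAD-like
  re-depolarization.

The classifier input is the raw beat-indexed series of one biomarker over
the final 500 of 1,000 beats — no variance reduction and no rescaling at
this stage.

## The CNN classifier

Six stages of 1-D convolutions (5 filters, kernel 2, stride 1, valid
padding everywhere) grouped 4/3/2/2/1/1 with max-pooling 2/2/2/2/4/4 at
stride 2, batch normalization at the end of stage 1, then flatten → 20%
dropout → dense 10 (ReLU) → dense 3 (softmax).  For input length 500 the
stage outputs are 248/122/60/29/13/5, so the flatten is exactly 5
time-steps × 5 channels = 25; valid padding is the only scheme consistent
with that arithmetic.  Training: categorical cross-entropy, Adam with
learning rate 1e-5, batches of 20, 300 epochs, 10-fold sample-stratified
cross-validation; the retained model is the fold maximising the mean of
training and validation accuracy, ties broken by lower validation loss.
Label encoding high=0, intermediate=1, low=2 is persisted with the model.
All randomness (fold split, shuffling, initialization, dropout) derives
from one config seed.

Two initialization choices matter at this learning rate and were made
deliberately.  With Adam, each weight moves at most ≈ lr per step, i.e.
O(0.1) over the whole schedule, so the network trains in a
near-initialization regime and the quality of the initial feature map is
load-bearing.  (1) The first-stage convolutions use He initialization, but
the deeper convolutions are Dirac/identity-initialized (identity channel
map plus 0.01 noise): at initialization the stack then acts as a
multi-scale max-pooled reader of the stage-1 features instead of a deep
random projection, which removes the flat, information-destroying regions
a random narrow ReLU stack otherwise develops, and lets the small trained
increments act on features that already separate the input.  (2) The
softmax head is zero-initialized so the logits start at zero and are
shaped entirely by training rather than dominated by a random head the
schedule cannot undo.  No input rescaling is applied (the open question of
whether the series should be z-scored is resolved as "no"): the batch-norm
layer adapts the scale internally, and experiments with affine input
rescaling moved the failure between classes rather than removing it.

Inference is dropout-free and deterministic; predicted probabilities sum
to 1 within 1e-6.

## Evaluation

The test pool holds every variability series of each test drug.  One
iteration draws one series per drug uniformly at random, predicts all
drugs, and scores: one-vs-rest ROC AUC per class from the class
probabilities (Mann–Whitney form, ties 0.5), and from the argmax labels
per-class diagnostic likelihood ratios LR+ = sens/(1−spec), LR− =
(1−sens)/spec, overall accuracy, and macro-averaged F1.  Division by zero
yields +Inf (reported as such); 0/0 yields a missing value skipped in
summaries.  10,000 iterations are summarised as median (min–max) per
metric, with medians taken over the extended real line so an "Inf" median
is representable.  Because inference is deterministic, predictions are
computed once per unique series and iterations only resample prediction
rows; per-iteration records are retained so summaries can be recomputed
without re-prediction.

## Synthetic data

The synthetic-data module generates every input the pipeline needs:
dose-response tables with known ground-truth Hill parameters (Gaussian
noise, clipped to [0,1]), the 28-drug CiPA reference fixture (12 train /
16 test; test split 4 high / 7 intermediate / 5 low), and
class-conditioned variability pools.

A pooled series is a stationary AR(1) process around a drug-level mean
(class mean + per-drug N(0, 0.02) offset) plus an optional even/odd-beat
alternans component.  Class defaults, on the qInward scale (no drug = 1):

| class        | mean | sd    | lag-1 autocorr. | alternans |
|--------------|------|-------|-----------------|-----------|
| high         | 0.95 | 0.03  | 0.5             | 0.05      |
| intermediate | 0.82 | 0.02  | 0.7             | 0.0       |
| low          | 0.62 | 0.04  | 0.3             | 0.0       |

The rationale: predominantly-hERG blockers (high risk) barely depress the
inward charge but destabilise repolarization at slow pacing, which appears
as beat-to-beat alternation; calcium-channel blockers (typically low risk)
depress qInward strongly and, under strong multi-channel block, produce
larger and less correlated beat-to-beat fluctuation; intermediate-risk
drugs sit between, with smooth strongly-autocorrelated drift.  This is the
minimal structure that carries class information in both the level and the
beat-to-beat texture of the series — the premise the classifier is built
on.  It makes no claim of quantitative physiological fidelity: passing
tests on these pools demonstrates that the pipeline's plumbing, training
and evaluation machinery work end-to-end on separable data, not that the
classifier would achieve the same performance on simulation-derived or
measured data.

## Problem sizes used in tests and acceptance checks

The full study configuration (2,000 posterior samples × 4 concentrations ×
1,000 beats per drug, 300 training epochs) is cluster-scale.  The package
runs the structural cardinalities at full size (2,000 Hill samples, 8,000
block sets, 600 training rows, 128,000-series test pool, 500-point windows
from a 1,000-beat run, 10,000 test iterations) and scales down only the
expensive stages: unit-test simulations use 20–60 beats (justified by the
model's fast approach to its limit cycle), and the end-to-end
train-and-evaluate check uses 120 epochs with all other hyperparameters as
printed, 200-series pools per drug, and a 1,000-iteration repeated test.

## Known limitations

* The reduced myocyte model reproduces qualitative block responses, not
  the quantitative biomarker values of detailed human-ventricular models;
  anything depending on absolute APD/qNet magnitudes should treat its
  outputs as illustrative.
* Fixed heart rate (CL 2,000 ms); no rate adaptation, mechano-electric
  feedback, temperature effects, or state-dependent (dynamic) drug
  binding.
* The deterministic model produces nearly constant steady-state biomarker
  series; the class-conditioned variability pools are the intended input
  for classifier training and evaluation.
* At the printed learning rate the CNN trains in a near-initialization
  regime; classification quality depends materially on the documented
  initialization scheme and on cross-validation fold selection.
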