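# Methods

## The transfer problem

One EEG acquisition domain (a species, modality and device) supplies
labeled seizure/non-seizure clips; a second domain supplies few or none.
The domains disagree in montage size, sampling rate, amplitude scale and
per-subject sensor mixing, and a classifier trained naively on the source
domain transfers poorly. The framework aligns the two domains in the
input, feature and output spaces simultaneously and trains a single
compact convolutional detector on the union of what is available.

Clips are `(C, T)` matrices (channels × samples, microvolts) with binary
labels; evaluation is clip-level AUC per target subject, averaged over
subjects within a run and over seeded repeats across runs (3 by default).

## The three alignments

**Input space.** (1) *Euclidean alignment*: for each subject,
`R̄ = (1/n) Σ X_i X_iᵀ` over all of that subject's clips, symmetrized and
diagonally loaded only when near-singular (relative floor `ε = 1e-6` of
the mean eigenvalue); each clip becomes `R̄^(-1/2) X_i` via
eigendecomposition with eigenvalue flooring. The statistic uses no labels,
so it is equally legitimate for unlabeled test subjects. The transform is
idempotent and invariant to per-subject rescaling. (2) *Channel
projection*: when montages differ, a learnable `C_out × C_in` matrix
(no bias, no nonlinearity) maps the wider montage down per time sample.
It is initialized to the selection matrix of the first `C_out` channels,
so training starts exactly at the truncation baseline; richer variants
were deliberately excluded. The backbone is always built at the lower
channel count, and the wider domain is always the one projected.

**Feature space.** A domain-adaptation term computed per step between a
labeled source batch and an unlabeled target batch. Default: minimum
class confusion on the target logits — probabilities at temperature
`τ_mcc = 2.5`, entropy-derived certainty weights normalized to sum to the
batch size, row-normalized class-confusion matrix, loss = mean
off-diagonal mass (bounded by `(K-1)/K`). Alternative: biased multi-kernel
MMD² with five Gaussian kernels at bandwidth multipliers
{0.25, 0.5, 1, 2, 4} on the median-heuristic base bandwidth (held constant
with respect to gradients).

**Output space.** Logit-level knowledge distillation between the two
input-unification strategies of the shared backbone: the projection branch
(which sees the full montage and therefore more information) acts as the
teacher, the channel-selection branch as the student;
`KD = mean_b KL(p_teacher || p_student) · τ²` at `τ_kd = 2`, teacher
gradient-blocked. Both branches also receive supervised cross-entropy —
they are alternative front ends of one model, not an auxiliary probe.
The reverse and mutual directions remain available
(`MethodConfig.kd_direction`).

**Objective.** `L = CE + λ·KD + β·DA` with `λ = β = 1`. Both weights ramp
linearly from zero over the first half of training so the supervised
signal establishes a working classifier before the alignment terms act on
it; without the warm-up the unsupervised terms can entrench early
mistakes. Unlabeled target clips are used transductively (labels never
read — enforced and tested by label-permutation invariance of the trained
parameters); an `inductive` flag restricts the model to the labeled pools.

## Backbone and training

EEGNet-8,2: temporal convolution (`F1 = 8` filters, kernel = half the
sampling rate, i.e. 0.5 s), batch norm, depthwise spatial filtering
(`D = 2` per temporal filter, collapsing the channel axis), batch norm,
ELU, average pooling ×4, dropout 0.25, separable temporal convolution
(16 taps, `F2 = 16`), batch norm, ELU, pooling ×8, dropout, linear
classifier to two logits. Convolutions have no biases (batch norm follows
them). At 6 channels × 256 samples this is 1 970 parameters.

Optimization: Adam, learning rate `1e-3`, batch 64 per domain, 20–35
epochs (35 is the package default — the point at which the benchmark's
loss curves flatten; all experiments here are desk-scale, minutes per
run). The stack is float32 NumPy with an in-house reverse-mode autodiff
engine; temporal convolutions run as single-precision FFT correlations
(circular size ≥ T+K−1, so exact), with each spectrum computed once and
shared between the forward pass and both gradients. Every primitive's
gradient is finite-difference tested. Single-threaded NumPy plus a single
seeded generator per run (initialization, batching, dropout, repeats) make
training bit-reproducible; checkpoints from two runs at the same seed are
identical byte for byte.

Sampling-rate mismatches are resolved by polyphase-resampling both domains
to the lower rate (no fabricated high-frequency content). Chronological
label splits take, per subject and per class, the first `⌈l%·n⌉` clips as
the labeled pool, so no test clip ever precedes a same-subject same-class
training clip. Subjects whose test pool lacks a class are skipped and
logged. Ties in AUC scoring receive half credit (Mann–Whitney convention).

## The synthetic benchmark

`n_latent = 4` latent sources per clip: unit-variance 1/f background, a
per-clip level drawn log-normally (σ = 0.25 dex) to emulate
nonstationarity. Seizure clips add to half the sources a 10–25 Hz
oscillation with random frequency, phase and amplitude modulation, scaled
so the expected clip-variance ratio ictal/background equals
`seizure_gain² = 2.25`, with its own log-normal intensity jitter
(σ = 0.25 dex). Independently of the label, 20 % of clips carry a
low-frequency (1–6 Hz) artifact burst of comparable amplitude
(`artifact_gain = 2.2`) on one source — the movement-like events that make
raw amplitude an unreliable seizure marker in practice. The ictal
signature is therefore the *band-limited rhythm*, not loudness: a
band-power-fraction oracle on the sensors scores ≈ 0.96 AUC per subject
while a pure variance threshold does much worse.

Each domain observes the latent process through per-subject lead fields —
standard-normal matrices times a per-subject global gain drawn log-uniform
from [0.1, 10], the device/subject amplitude heterogeneity that
per-subject whitening exists to remove. Source: 16 channels at 400 Hz;
target: 6 channels at 256 Hz; 4 subjects × 200 one-second clips per
domain; seizure fraction 0.3; white sensor noise at 10 dB SNR. The whole
benchmark is a pure function of `SimConfig.seed`.

What the generator does *not* model: spike-wave morphology, biophysical
head geometry, channel-correlated noise, seizure evolution across clips,
inter-ictal discharges. Passing the benchmark therefore demonstrates that
the alignment machinery recovers a cross-domain spectral signature under
montage/scale/rate heterogeneity and amplitude confounds — not clinical
performance on real recordings. On real data the approximate-entropy
direction of the ictal contrast may also differ from this generator's
(the benchmark only guarantees the amplitude/band-power contrast, and its
own ApEn behaviour is reported empirically by `msa qc`, not asserted).

## The ladder

The built-in experiment (`msa ablate`, `msalign.benchmark.run_benchmark`)
trains four rungs under identical budgets with three seeded repeats each:
`none` (channel truncation, no alignment — equivalently the source-only
baseline in the unsupervised scenario), `+EA`, `+DA` (EA + projection +
MCC) and `full` (adds distillation). The expected reading is a
non-decreasing mean AUC across rungs and a clear gap between `none` and
the latent oracle — the benchmark's analogue of the ordering
source-only < standalone alignments < full MSA.

## Numerical and design notes

- Preprocessing defaults (for continuous recordings): 1 s non-overlapping
  clips, zero-phase 4th-order Butterworth 0.5–70 Hz (demean + Gustafsson
  edge handling, which keeps stop-band leakage out of short clips), notch
  off. Majority-overlap clip labelling; exact ties labelled seizure
  (favouring sensitivity). Half-open windows, 0-based indexing.
- ApEn: classical convention — Chebyshev distance, self-matches included,
  `m = 2`, `r = 0.2·SD`; translation-invariant, and scale-invariant with
  the relative tolerance.
- Spectrograms: consecutive Hann windows (1 s, 50 % overlap), one-sided
  PSD in dB floored at −120 dB.
- Batch norm: ε = 1e-3, momentum 0.1; training-mode statistics are
  per-branch, running statistics shared; evaluation always uses running
  statistics.
- The internal container is one float32 `.npy` stack per subject plus a
  JSON sidecar (`n_channels`, `sampling_rate`, `modality`, `species`,
  per-subject labels and start times); round-trips are bit-exact.

## Known limitations

- The projection is strictly linear; montages whose relationship is
  nonlinear (e.g. scalp vs depth electrodes with very different reference
  schemes) may need the richer variants this package intentionally omits.
- MCC assumes the target carries both classes in roughly stable
  proportions within a batch; severe class imbalance would need
  batch-balancing.
- The benchmark's difficulty is calibrated, not learned from real data;
  absolute AUCs on it do not forecast clinical numbers.
- With four subjects per domain, the severity of the simulated domain
  shift depends on the drawn subject gains and therefore varies across
  generator seeds; the ladder orderings are stable in the mean over
  repeats but not guaranteed at every individual seed.
- Training is CPU-bound NumPy: ideal for the desk-scale benchmark,
  not for multi-hour clinical corpora.
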