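# msalign — multi-space alignment for cross-species EEG seizure detection

Seizure detectors trained on one EEG dataset rarely transfer to another:
recordings differ in electrode count (e.g. a 16-electrode intracranial
canine montage vs. a 6-electrode human one), sampling rate, device gain and
subject physiology, and a model trained on one species' data degrades badly
on another's. `msalign` implements a multi-space alignment (MSA) framework
that closes these gaps in three spaces at once so labeled data from an
auxiliary domain (another species or modality) can power detection in a
target domain with few or no labels:

- **Input space** — per-subject *Euclidean alignment*: every subject's
  trials `X_i` are whitened by the inverse square root of the subject's
  mean trial covariance, `X_i ← R̄^(-1/2) X_i` with
  `R̄ = (1/n) Σ_i X_i X_iᵀ`, so all subjects share the identity reference
  covariance; plus a learnable linear channel projection ("ResizeNet",
  a `C_out × C_in` matrix applied per time sample, initialized to channel
  selection) that maps the wider montage onto the narrower one.
- **Feature space** — unsupervised domain adaptation between source and
  target batches: minimum class confusion (MCC) on unlabeled target logits
  by default, or multi-kernel maximum mean discrepancy (MMD) on features.
- **Output space** — knowledge distillation with temperature-scaled KL
  divergence between the two input-unification branches of the shared
  backbone (the full-montage projection branch teaches the
  channel-selection branch).

The combined objective is `L = CE + λ·KD + β·DA` with `λ = β = 1`. The
feature extractor is the compact convolutional EEGNet-8,2 with a linear
classifier; everything runs on a small NumPy reverse-mode autodiff engine
(`msalign.nn`) — no deep-learning framework required. Performance is
measured as the area under the ROC curve (AUC) of the seizure probability,
per target subject, with chronological label splits that prevent temporal
leakage.

Because the corpora this kind of framework targets are large clinical
downloads, the package ships a synthetic two-domain benchmark
(`msalign.synthetic_eeg`): both domains observe the same latent seizure
process (pink-noise background, band-limited ictal rhythm, artifact bursts,
nonstationary levels) through different per-subject lead fields, montage
sizes (16 vs 6 channels) and sampling rates (400 vs 256 Hz), so every
pipeline stage is testable end to end.

## Worked example

```bash
python examples/04_train_transfer.py
```

trains an unaligned source-only baseline and the full MSA model on a
reduced benchmark (2 subjects per domain) and prints:

```
per-subject AUC on the target domain (unsupervised transfer):
  target_s0: source-only 0.582 -> full MSA 0.650
  target_s1: source-only 0.678 -> full MSA 0.714
mean: source-only 0.630 -> full MSA 0.682
```

Each line is one held-out target subject; the AUC is the probability that
a random seizure clip outscores a random background clip for that subject.
Source-only trains on the 16-channel domain with channels truncated and no
alignment; full MSA adds whitening, the learned projection, MCC adaptation
and distillation, and lifts every subject. The other scripts in
`examples/` demonstrate the generator, whitening, the three losses and the
signal diagnostics individually.

The same workflows are available from the shell:

```bash
msa simulate --seed 0 --out bench/
msa train --source bench/source --target bench/target --out model.npz --results res.json
msa evaluate --model model.npz --data bench/target
msa ablate --seed 0 --out ladder.json     # none -> +EA -> +DA -> full MSA
msa qc --in bench/target --out qc/
```

## Layout

| module | contents |
| --- | --- |
| `msalign.data_io` | `Trial`/`DomainDataset` containers, on-disk format, filtering, resampling, clip segmentation, optional EDF import |
| `msalign.euclidean_alignment` | per-subject covariance whitening |
| `msalign.models` | ResizeNet channel projection, EEGNet backbone, checkpoints |
| `msalign.alignment_losses` | CE, KD, MMD, MCC and the combined objective |
| `msalign.trainer` | transfer scenarios, chronological splits, baselines, AUC evaluation, seeded repeats |
| `msalign.synthetic_eeg` | the two-domain benchmark generator |
| `msalign.diagnostics` | approximate entropy, PSD spectrograms, QC reports |
| `msalign.nn` | NumPy autodiff, conv/batch-norm primitives, Adam |

See `docs/methods.md` for the model, the generator's assumptions and the
numerical choices.
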