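"""Train a cross-domain transfer model and compare it with the unaligned
baseline.

A reduced version of the benchmark (2 subjects per domain) keeps this
example under a couple of minutes; the full study conditions live in
`msalign.benchmark.run_benchmark` / `msa ablate`.
"""

import numpy as np

from msalign import SimConfig, TrainConfig, generate_transfer_pair, run_experiment
from msalign.trainer import MSA_METHOD, MethodConfig

cfg = SimConfig(seed=0, n_subjects=2, clips_per_subject=100)
task = generate_transfer_pair(cfg)
tc = TrainConfig(epochs=20, seed=0)

source_only = MethodConfig(name="source_only", use_ea=False,
                           use_resizenet=False, da="none", kd="none",
                           use_target_labels=False)
baseline_aucs, _ = run_experiment(task, source_only, train_cfg=tc)
msa_aucs, _ = run_experiment(task, MSA_METHOD, train_cfg=tc)

print("per-subject AUC on the target domain (unsupervised transfer):")
for sid in sorted(msa_aucs):
    print(f"  {sid}: source-only {baseline_aucs[sid]:.3f} -> "
          f"full MSA {msa_aucs[sid]:.3f}")
print(f"mean: source-only {np.mean(list(baseline_aucs.values())):.3f} -> "
      f"full MSA {np.mean(list(msa_aucs.values())):.3f}")
print("Source-only trains on the wide-montage domain with channels truncated")
print("and no alignment; full MSA adds per-subject whitening, the learnable")
print("channel projection, class-confusion adaptation and distillation.")
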