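"""The three alignment losses and their composition.

KD aligns the output space (predictions of the channel-projection and
channel-selection branches), MMD/MCC align the feature space across
domains, and the total objective is CE + lambda*KD + beta*DA with
lambda = beta = 1.
"""

import numpy as np

from msalign import LossWeights, cross_entropy, kd_loss, mcc_loss, mmd_loss, msa_total_loss

rng = np.random.default_rng(0)

teacher = np.array([[2.0, -1.0], [-1.5, 1.0], [3.0, 0.0]])
student_far = np.zeros((3, 2))
student_near = teacher * 0.9
print(f"KD(far student)  = {kd_loss(student_far, teacher, tau=2.0):.4f}")
print(f"KD(near student) = {kd_loss(student_near, teacher, tau=2.0):.4f}")
print("-> the KL term shrinks as the student's softened predictions")
print("   approach the teacher's.\n")

same = rng.standard_normal((32, 8))
shifted = rng.standard_normal((32, 8)) + 2.0
print(f"MMD(same distribution)    = {mmd_loss(same, rng.standard_normal((32, 8))):.4f}")
print(f"MMD(mean-shifted domains) = {mmd_loss(same, shifted):.4f}")
print("-> kernel mean discrepancy is near zero when source and target")
print("   features match and grows with the domain gap.\n")

confident = np.array([[8.0, -8.0], [-8.0, 8.0]] * 4)
uncertain = rng.standard_normal((8, 2)) * 0.2
print(f"MCC(confident target predictions) = {mcc_loss(confident, tau=2.5):.4f}")
print(f"MCC(ambiguous target predictions) = {mcc_loss(uncertain, tau=2.5):.4f}")
print("-> class confusion penalizes ambiguous unlabeled-target predictions.\n")

ce = cross_entropy(np.array([[1.0, -1.0]]), [0])
total = msa_total_loss(ce, 0.2, 0.1, LossWeights())
print(f"total = CE({ce:.4f}) + 1*KD(0.2) + 1*DA(0.1) = {total:.4f}")
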