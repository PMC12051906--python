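"""Input-space alignment by per-subject covariance whitening.

For each subject, the reference matrix is the arithmetic mean of the trial
covariances, R = (1/n) sum_i X_i X_i^T.  Every trial is then replaced by
R^(-1/2) X, which makes the subject's mean trial covariance the identity.
All subjects thereby share one reference scale, removing subject- and
device-specific spatial covariance structure before any learning happens.
The statistic is label-free, so it may be computed on unlabeled test
subjects as well.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_io import DomainDataset, Trial

__all__ = ["AlignmentState", "mean_covariance", "inv_sqrt_spd", "euclidean_align"]

DEFAULT_EPSILON = 1e-6


@dataclass(frozen=True)
class AlignmentState:
    """Per-subject whitening state: reference covariance and its inverse
    square root."""

    mean_cov: np.ndarray
    whitener: np.ndarray
    epsilon: float = DEFAULT_EPSILON

    def to_dict(self) -> dict:
        return {
            "mean_cov": self.mean_cov.tolist(),
            "whitener": self.whitener.tolist(),
            "epsilon": self.epsilon,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AlignmentState":
        return cls(np.asarray(d["mean_cov"]), np.asarray(d["whitener"]),
                   float(d["epsilon"]))


def mean_covariance(trials: list[Trial], epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Mean trial covariance (1/n) sum_i X_i X_i^T, symmetrized, with a
    relative diagonal loading applied only when near-singular."""
    if not trials:
        raise ValueError("need at least one trial")
    C = trials[0].n_channels
    for t in trials:
        if t.n_channels != C:
            raise ValueError("trials have inconsistent channel counts")
    acc = np.zeros((C, C), dtype=np.float64)
    for t in trials:
        X = t.signal.astype(np.float64)
        acc += X @ X.T
    R = acc / len(trials)
    R = 0.5 * (R + R.T)
    scale = np.trace(R) / C
    if scale <= 0:
        scale = 1.0
    if np.linalg.eigvalsh(R)[0] < epsilon * scale:
        R = R + epsilon * scale * np.eye(C)
    return R


def inv_sqrt_spd(M: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Inverse matrix square root of an SPD matrix via eigendecomposition,
    flooring eigenvalues at ``epsilon`` times the mean eigenvalue."""
    M = np.asarray(M, dtype=np.float64)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(M, M.T, atol=1e-8 * max(1.0, np.abs(M).max())):
        raise ValueError("matrix must be symmetric")
    w, V = np.linalg.eigh(M)
    floor = epsilon * max(w.mean(), np.finfo(np.float64).tiny)
    w = np.maximum(w, floor)
    return (V * (w ** -0.5)) @ V.T


def euclidean_align(
    dataset: DomainDataset, epsilon: float = DEFAULT_EPSILON
) -> tuple[DomainDataset, dict[str, AlignmentState]]:
    """Whiten every trial by its own subject's reference matrix.

    Returns the aligned dataset (labels, ordering and metadata unchanged)
    and the per-subject :class:`AlignmentState` map.  After alignment each
    subject's mean trial covariance is the identity, so the transform is
    idempotent and invariant to per-subject amplitude scaling.
    """
    states: dict[str, AlignmentState] = {}
    aligned: list[Trial] = []
    for sid in dataset.subjects:
        trials = dataset.subject_trials(sid)
        R = mean_covariance(trials, epsilon)
        S = inv_sqrt_spd(R, epsilon)
        states[sid] = AlignmentState(mean_cov=R, whitener=S, epsilon=epsilon)
        S32 = S.astype(np.float64)
        for t in trials:
            aligned.append(replace(t, signal=(S32 @ t.signal.astype(np.float64)).astype(np.float32)))
    out = DomainDataset(
        trials=aligned,
        n_channels=dataset.n_channels,
        sampling_rate=dataset.sampling_rate,
        modality=dataset.modality,
        species=dataset.species,
        domain_id=dataset.domain_id,
    )
    return out, states
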