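"""The multi-space alignment objective.

Total loss = CE + lambda * KD + beta * DA, with both trade-off weights
defaulting to 1:

* CE    — softmax cross-entropy on labeled logits (output space, supervised);
* KD    — temperature-scaled KL divergence between the channel-selection
          and channel-projection branches of the shared backbone
          (output-space alignment); the teacher side is gradient-blocked;
* DA    — an unsupervised domain-adaptation term: minimum class confusion
          (MCC) on unlabeled target logits, or multi-kernel maximum mean
          discrepancy (MMD) between source and target features.

Every loss accepts plain NumPy arrays (evaluated in float64, returning a
float) or autograd tensors (returning a float32 graph node for training);
the two routes implement the same formulas and are cross-checked in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, as_tensor

__all__ = [
    "LossWeights",
    "cross_entropy",
    "kd_loss",
    "mmd_loss",
    "mcc_loss",
    "msa_total_loss",
]

MMD_BANDWIDTH_MULTIPLIERS = (0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class LossWeights:
    """Trade-off weights and temperatures of the combined objective."""

    lambda_kd: float = 1.0
    beta_da: float = 1.0
    tau_kd: float = 2.0
    tau_mcc: float = 2.5

    def __post_init__(self):
        if self.lambda_kd < 0 or self.beta_da < 0:
            raise ValueError("loss weights must be non-negative")
        if self.tau_kd <= 0 or self.tau_mcc <= 0:
            raise ValueError("temperatures must be positive")


def _log_softmax64(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


# ----------------------------------------------------------------------
# cross-entropy
# ----------------------------------------------------------------------

def cross_entropy(logits, labels) -> float | Tensor:
    """Mean softmax cross-entropy; ``labels`` are integer class indices."""
    labels = np.asarray(labels, dtype=np.int64)
    if isinstance(logits, Tensor):
        B, K = logits.shape
        onehot = np.zeros((B, K), dtype=np.float32)
        onehot[np.arange(B), labels] = 1.0
        logp = logits.log_softmax(axis=1)
        return -(logp * Tensor(onehot)).sum() * (1.0 / B)
    z = np.asarray(logits, dtype=np.float64)
    logp = _log_softmax64(z)
    return float(-logp[np.arange(len(z)), labels].mean())


# ----------------------------------------------------------------------
# knowledge distillation
# ----------------------------------------------------------------------

def kd_loss(student_logits, teacher_logits, tau: float = 2.0) -> float | Tensor:
    """Distillation loss: mean_b KL(soft-teacher || soft-student) * tau^2.

    Softening is softmax of logits/tau; the teacher is treated as a
    constant (no gradient flows into it).
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    s_shape = np.shape(student_logits.data if isinstance(student_logits, Tensor)
                       else student_logits)
    t_shape = np.shape(teacher_logits.data if isinstance(teacher_logits, Tensor)
                       else teacher_logits)
    if s_shape != t_shape:
        raise ValueError("student and teacher logits must have the same shape")
    if s_shape[1] < 2:
        raise ValueError("need at least two classes")
    B = s_shape[0]
    if isinstance(student_logits, Tensor) or isinstance(teacher_logits, Tensor):
        s = as_tensor(student_logits)
        t = as_tensor(teacher_logits).detach()
        log_ps = (s * (1.0 / tau)).log_softmax(axis=1)
        log_pt_data = _log_softmax64(t.data.astype(np.float64) / tau)
        pt = np.exp(log_pt_data).astype(np.float32)
        kl = (Tensor(pt) * (Tensor(log_pt_data) - log_ps)).sum() * (1.0 / B)
        return kl * (tau * tau)
    log_ps = _log_softmax64(np.asarray(student_logits, np.float64) / tau)
    log_pt = _log_softmax64(np.asarray(teacher_logits, np.float64) / tau)
    pt = np.exp(log_pt)
    return float((pt * (log_pt - log_ps)).sum() / B * tau * tau)


# ----------------------------------------------------------------------
# maximum mean discrepancy
# ----------------------------------------------------------------------

def _pairwise_sq_dists_t(a: Tensor, b: Tensor) -> Tensor:
    aa = (a ** 2.0).sum(axis=1, keepdims=True)
    bb = (b ** 2.0).sum(axis=1, keepdims=True)
    return aa + bb.T - (a @ b.T) * 2.0


def _mmd_base(d_ss, d_tt, d_st, base_bandwidth) -> float:
    if base_bandwidth is not None:
        return float(base_bandwidth)
    pooled = np.concatenate([np.ravel(d_ss), np.ravel(d_tt), np.ravel(d_st)])
    base = float(np.median(pooled))
    return base if base > 0 else 1.0


def mmd_loss(
    source_feats,
    target_feats,
    bandwidth_multipliers: tuple[float, ...] = MMD_BANDWIDTH_MULTIPLIERS,
    base_bandwidth: float | None = None,
) -> float | Tensor:
    """Biased multi-kernel MMD^2 between two feature samples.

    Gaussian kernels share a base bandwidth set by the median heuristic
    (median of all pairwise squared distances of the pooled sample, held
    constant w.r.t. gradients) scaled by each multiplier; the estimate is
    mean(K_ss) + mean(K_tt) - 2 mean(K_st), averaged over kernels.  Pass
    ``base_bandwidth`` to bypass the heuristic (k(a,b) =
    exp(-|a-b|^2 / (mult * base))).
    """
    is_tensor = isinstance(source_feats, Tensor) or isinstance(target_feats, Tensor)
    if is_tensor:
        s, t = as_tensor(source_feats), as_tensor(target_feats)
        if s.ndim != 2 or t.ndim != 2:
            raise ValueError("features must be 2-D (batch, feature)")
        if s.shape[0] < 2 or t.shape[0] < 2:
            raise ValueError("need at least two samples per domain")
        d_ss = _pairwise_sq_dists_t(s, s)
        d_tt = _pairwise_sq_dists_t(t, t)
        d_st = _pairwise_sq_dists_t(s, t)
        base = _mmd_base(d_ss.data, d_tt.data, d_st.data, base_bandwidth)
        total = None
        for mult in bandwidth_multipliers:
            gamma = 1.0 / (mult * base)
            term = (
                (d_ss * -gamma).exp().mean()
                + (d_tt * -gamma).exp().mean()
                - (d_st * -gamma).exp().mean() * 2.0
            )
            total = term if total is None else total + term
        return total * (1.0 / len(bandwidth_multipliers))
    s = np.asarray(source_feats, dtype=np.float64)
    t = np.asarray(target_feats, dtype=np.float64)
    if s.ndim != 2 or t.ndim != 2:
        raise ValueError("features must be 2-D (batch, feature)")
    if s.shape[0] < 2 or t.shape[0] < 2:
        raise ValueError("need at least two samples per domain")

    def sq_dists(a, b):
        return ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)

    d_ss, d_tt, d_st = sq_dists(s, s), sq_dists(t, t), sq_dists(s, t)
    base = _mmd_base(d_ss, d_tt, d_st, base_bandwidth)
    vals = []
    for mult in bandwidth_multipliers:
        gamma = 1.0 / (mult * base)
        vals.append(
            np.exp(-gamma * d_ss).mean()
            + np.exp(-gamma * d_tt).mean()
            - 2.0 * np.exp(-gamma * d_st).mean()
        )
    return float(np.mean(vals))


# ----------------------------------------------------------------------
# minimum class confusion
# ----------------------------------------------------------------------

def mcc_loss(target_logits, tau: float = 2.5) -> float | Tensor:
    """Minimum class confusion on unlabeled target logits.

    Probabilities Y = softmax(logits/tau); per-example certainty weights
    decrease with prediction entropy and are normalized to sum to the batch
    size; the class-confusion matrix C = Y^T diag(w) Y is row-normalized and
    the loss is its mean off-diagonal mass, sum_{j != j'} C_jj' / K.
    Bounded in [0, (K-1)/K].
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    shape = np.shape(target_logits.data if isinstance(target_logits, Tensor)
                     else target_logits)
    B, K = shape
    if B < 2:
        raise ValueError("need at least two target examples")
    if isinstance(target_logits, Tensor):
        z = target_logits
        logy = (z * (1.0 / tau)).log_softmax(axis=1)
        Y = logy.exp()
        entropy = -(Y * logy).sum(axis=1)
        cert = 1.0 + (-entropy).exp()
        w = cert * float(B) * cert.sum() ** -1.0
        Yw = Y * w.reshape(B, 1)
        Cc = Y.T @ Yw
        Cn = Cc / Cc.sum(axis=1, keepdims=True)
        off = Cn.sum() - (Cn * Tensor(np.eye(K, dtype=np.float32))).sum()
        return off * (1.0 / K)
    z = np.asarray(target_logits, dtype=np.float64)
    logy = _log_softmax64(z / tau)
    Y = np.exp(logy)
    entropy = -(Y * logy).sum(axis=1)
    cert = 1.0 + np.exp(-entropy)
    w = B * cert / cert.sum()
    Cc = Y.T @ (Y * w[:, None])
    Cn = Cc / Cc.sum(axis=1, keepdims=True)
    return float((Cn.sum() - np.trace(Cn)) / K)


# ----------------------------------------------------------------------
# composition
# ----------------------------------------------------------------------

def msa_total_loss(ce, kd, da, w: LossWeights) -> float | Tensor:
    """Combined objective: ce + lambda * kd + beta * da."""
    if any(isinstance(x, Tensor) for x in (ce, kd, da)):
        return as_tensor(ce) + as_tensor(kd) * w.lambda_kd + as_tensor(da) * w.beta_da
    return float(ce) + w.lambda_kd * float(kd) + w.beta_da * float(da)
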