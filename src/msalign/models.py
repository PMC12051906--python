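"""Learnable components: channel projection, EEGNet backbone, classifier.

Heterogeneous montages are unified in the input space by a learnable linear
channel projection ("ResizeNet"): a C_out x C_in matrix applied per time
sample (a width-1 convolution across channels), initialized to the
channel-selection matrix so training starts exactly at the truncation
baseline.  The feature extractor is the standard compact convolutional
EEGNet-8,2: temporal convolution, depthwise spatial filtering, separable
temporal convolution, batch-norm/ELU/average-pooling throughout, followed by
a fully connected classifier to two logits (non-seizure, seizure).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "ResizeNet",
    "EEGNetConfig",
    "EEGNet",
    "MSAModel",
    "truncate_channels",
    "resize_project",
    "eegnet_logits",
    "save_checkpoint",
    "load_checkpoint",
]

_CHECKPOINT_VERSION = 1


def truncate_channels(signal: np.ndarray, c_out: int) -> np.ndarray:
    """Channel-selection baseline: keep the first ``c_out`` rows."""
    if c_out <= 0:
        raise ValueError("c_out must be positive")
    if c_out > signal.shape[-2]:
        raise ValueError(f"cannot select {c_out} channels from {signal.shape[-2]}")
    return signal[..., :c_out, :]


class ResizeNet(nn.Module):
    """Linear channel projection mapping C_in-channel trials to C_out channels.

    ``weight`` is (C_out, C_in); at init it is the selection matrix picking
    the first C_out channels, so the projection coincides with truncation
    until training moves it.
    """

    def __init__(self, c_in: int, c_out: int, bias: bool = False):
        super().__init__()
        if c_out > c_in:
            raise ValueError("projection must not increase the channel count")
        w = np.zeros((c_out, c_in), dtype=np.float32)
        w[:, :c_out] = np.eye(c_out)
        self.weight = nn.Parameter(w)
        self.bias = nn.Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-2] != self.weight.shape[1]:
            raise ValueError(
                f"expected {self.weight.shape[1]} input channels, got {x.shape[-2]}"
            )
        out = nn.conv_pointwise(x, self.weight)
        if self.bias is not None:
            out = out + self.bias.reshape(1, -1, 1)
        return out


def resize_project(params: ResizeNet, signal: np.ndarray) -> np.ndarray:
    """Apply the channel projection to one (C_in, T) trial or a (B, C_in, T)
    batch, returning plain arrays."""
    arr = np.asarray(signal, dtype=np.float32)
    single = arr.ndim == 2
    if single:
        arr = arr[None]
    out = params(Tensor(arr)).data
    return out[0] if single else out


@dataclass(frozen=True)
class EEGNetConfig:
    """EEGNet-8,2 hyperparameters.

    ``kernel_length`` (temporal filter taps) defaults to half the sampling
    rate, i.e. a 0.5 s kernel; F2 = F1 * D by the separable-conv convention.
    """

    n_channels: int
    n_samples: int
    F1: int = 8
    D: int = 2
    kernel_length: int = 128
    sep_kernel_length: int = 16
    pool1: int = 4
    pool2: int = 8
    dropout: float = 0.25
    n_classes: int = 2

    @property
    def F2(self) -> int:
        return self.F1 * self.D

    @property
    def feature_dim(self) -> int:
        return self.F2 * (self.n_samples // self.pool1 // self.pool2)

    def __post_init__(self):
        if self.kernel_length < 2:
            raise ValueError("temporal kernel needs at least 2 taps")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_samples // self.pool1 // self.pool2 < 1:
            raise ValueError("pooling consumes the whole time axis")


class EEGNet(nn.Module):
    """Compact convolutional EEG feature extractor + linear classifier."""

    def __init__(self, cfg: EEGNetConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        std1 = 1.0 / np.sqrt(cfg.kernel_length)
        self.conv_temporal_w = nn.Parameter(
            rng.normal(0.0, std1, size=(cfg.F1, cfg.kernel_length))
        )
        self.bn1 = nn.BatchNorm(cfg.F1, channel_axis=1)
        std2 = 1.0 / np.sqrt(cfg.n_channels)
        self.conv_spatial_w = nn.Parameter(
            rng.normal(0.0, std2, size=(cfg.F1, cfg.D, cfg.n_channels))
        )
        self.bn2 = nn.BatchNorm(cfg.F2, channel_axis=1)
        std3 = 1.0 / np.sqrt(cfg.sep_kernel_length)
        self.conv_sep_depth_w = nn.Parameter(
            rng.normal(0.0, std3, size=(cfg.F2, cfg.sep_kernel_length))
        )
        self.conv_sep_point_w = nn.Parameter(
            rng.normal(0.0, 1.0 / np.sqrt(cfg.F2), size=(cfg.F2, cfg.F2))
        )
        self.bn3 = nn.BatchNorm(cfg.F2, channel_axis=1)
        self.drop1 = nn.Dropout(cfg.dropout, rng)
        self.drop2 = nn.Dropout(cfg.dropout, rng)
        self.classifier = nn.Linear(cfg.feature_dim, cfg.n_classes, rng)

    def features(self, x: Tensor) -> Tensor:
        """(B, C, T) -> (B, feature_dim) flattened backbone output."""
        if x.shape[1] != self.cfg.n_channels:
            raise ValueError(
                f"expected {self.cfg.n_channels} channels, got {x.shape[1]}"
            )
        h = nn.conv_temporal(x, self.conv_temporal_w)      # (B, F1, C, T)
        h = self.bn1(h)
        h = nn.conv_depthwise_spatial(h, self.conv_spatial_w)  # (B, F2, T)
        h = self.bn2(h).elu()
        h = nn.avg_pool_time(h, self.cfg.pool1)
        h = self.drop1(h)
        h = nn.conv_depthwise_temporal(h, self.conv_sep_depth_w)
        h = nn.conv_pointwise(h, self.conv_sep_point_w)
        h = self.bn3(h).elu()
        h = nn.avg_pool_time(h, self.cfg.pool2)
        h = self.drop2(h)
        B = h.shape[0]
        return h.reshape(B, self.cfg.feature_dim)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        feats = self.features(x)
        return feats, self.classifier(feats)


@dataclass
class MSAModel:
    """The full multi-space alignment model: optional channel projection for
    the wider-montage domain, shared backbone and classifier, loss weights."""

    backbone: EEGNet
    resizenet: ResizeNet | None = None
    lambda_kd: float = 1.0
    beta_da: float = 1.0
    tau_kd: float = 2.0
    tau_mcc: float = 2.5

    def modules(self) -> list[nn.Module]:
        mods: list[nn.Module] = [self.backbone]
        if self.resizenet is not None:
            mods.append(self.resizenet)
        return mods

    def parameters(self) -> list[nn.Parameter]:
        return [p for m in self.modules() for p in m.parameters()]

    def train(self) -> None:
        for m in self.modules():
            m.train(True)

    def eval(self) -> None:
        for m in self.modules():
            m.eval()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"backbone.{k}": v for k, v in self.backbone.state_dict().items()}
        if self.resizenet is not None:
            state.update(
                {f"resizenet.{k}": v for k, v in self.resizenet.state_dict().items()}
            )
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.backbone.load_state_dict(
            {k[len("backbone."):]: v for k, v in state.items() if k.startswith("backbone.")}
        )
        if self.resizenet is not None:
            self.resizenet.load_state_dict(
                {k[len("resizenet."):]: v for k, v in state.items() if k.startswith("resizenet.")}
            )

    # ------------------------------------------------------------------
    def project(self, batch: np.ndarray | Tensor) -> Tensor:
        """Project a wider-montage batch down to the backbone's channels."""
        if self.resizenet is None:
            raise ValueError("model has no channel projection")
        x = batch if isinstance(batch, Tensor) else Tensor(np.asarray(batch, np.float32))
        return self.resizenet(x)

    def predict_proba(self, batch: np.ndarray, project: bool = False) -> np.ndarray:
        """Seizure-class probabilities for a (B, C, T) batch in eval mode."""
        self.eval()
        x = Tensor(np.asarray(batch, dtype=np.float32))
        if project:
            x = self.project(x)
        _, logits = self.backbone(x)
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        e = np.exp(z)
        return (e / e.sum(axis=1, keepdims=True))[:, 1]


def eegnet_logits(model: MSAModel, batch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic eval-mode forward pass: (features, logits) arrays."""
    model.eval()
    feats, logits = model.backbone(Tensor(np.asarray(batch, dtype=np.float32)))
    return feats.data, logits.data


# ----------------------------------------------------------------------
# checkpointing
# ----------------------------------------------------------------------

def save_checkpoint(model: MSAModel, path: str | Path) -> None:
    """Single-file .npz checkpoint with the config embedded as JSON."""
    path = Path(path)
    meta = {
        "version": _CHECKPOINT_VERSION,
        "backbone_cfg": asdict(model.backbone.cfg),
        "resizenet": None
        if model.resizenet is None
        else {
            "c_in": model.resizenet.weight.shape[1],
            "c_out": model.resizenet.weight.shape[0],
            "bias": model.resizenet.bias is not None,
        },
        "lambda_kd": model.lambda_kd,
        "beta_da": model.beta_da,
        "tau_kd": model.tau_kd,
        "tau_mcc": model.tau_mcc,
    }
    arrays = {k.replace(".", "/"): v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path) -> MSAModel:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        arrays = {k.replace("/", "."): npz[k] for k in npz.files if k != "__meta__"}
    if meta["version"] != _CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta['version']}")
    rng = np.random.default_rng(0)  # overwritten by the stored state below
    backbone = EEGNet(EEGNetConfig(**meta["backbone_cfg"]), rng)
    rn = None
    if meta["resizenet"] is not None:
        rn = ResizeNet(meta["resizenet"]["c_in"], meta["resizenet"]["c_out"],
                       bias=meta["resizenet"]["bias"])
    model = MSAModel(backbone=backbone, resizenet=rn,
                     lambda_kd=meta["lambda_kd"], beta_da=meta["beta_da"],
                     tau_kd=meta["tau_kd"], tau_mcc=meta["tau_mcc"])
    model.load_state_dict(arrays)
    return model
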