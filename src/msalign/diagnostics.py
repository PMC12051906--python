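"""Signal-level diagnostics: approximate entropy and PSD spectrograms.

These are the statistics used to check that seizure clips actually differ
from background activity — in regularity (ApEn) and in band power (the
spectrogram) — both for dataset QC and for validating the synthetic
benchmark's class contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .data_io import DomainDataset, Trial

__all__ = [
    "ApEnParams",
    "approximate_entropy",
    "psd_spectrogram",
    "class_contrast_report",
]

DB_FLOOR = -120.0


@dataclass(frozen=True)
class ApEnParams:
    """Approximate-entropy parameters: embedding dimension ``m`` and
    tolerance ``r`` (absolute, or a multiple of the signal SD when
    ``r_is_relative``).  m=2, r=0.2*SD are the field's defaults."""

    m: int = 2
    r: float = 0.2
    r_is_relative: bool = True

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r <= 0:
            raise ValueError("tolerance r must be positive")


def _phi(x: np.ndarray, m: int, r: float) -> float:
    """Phi^m(r): mean log of the fraction of templates within Chebyshev
    distance r (self-matches included, classical Pincus convention)."""
    n = len(x) - m + 1
    templates = np.lib.stride_tricks.sliding_window_view(x, m)  # (n, m)
    dist = np.abs(templates[:, None, :] - templates[None, :, :]).max(axis=2)
    counts = (dist <= r).mean(axis=1)
    return float(np.mean(np.log(counts)))


def approximate_entropy(x: np.ndarray, params: ApEnParams = ApEnParams()) -> float:
    """ApEn(m, r) = Phi^m(r) - Phi^{m+1}(r).

    Translation-invariant; with a relative tolerance also scale-invariant.
    Zero for constant series; larger for more irregular series.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if len(x) <= params.m + 1:
        raise ValueError(f"series length {len(x)} too short for m={params.m}")
    r = params.r * x.std() if params.r_is_relative else params.r
    if r == 0.0:  # constant series with relative tolerance
        return 0.0
    return _phi(x, params.m, r) - _phi(x, params.m + 1, r)


def psd_spectrogram(
    trial: Trial,
    rate: float,
    window_seconds: float = 1.0,
    overlap_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Consecutive Hann-windowed one-sided power spectra in dB.

    Returns ``(power_db, times, freqs)`` where ``power_db`` is
    (windows, freq bins), channel-averaged, floored at -120 dB.  Bin spacing
    is 1 / window_seconds.
    """
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    nperseg = int(round(window_seconds * rate))
    if nperseg > trial.n_samples:
        raise ValueError("window longer than the trial")
    noverlap = int(round(overlap_fraction * nperseg))
    freqs, times, Sxx = sps.spectrogram(
        trial.signal.astype(np.float64), fs=rate, window="hann",
        nperseg=nperseg, noverlap=noverlap, axis=1, mode="psd",
    )
    power = Sxx.mean(axis=0).T  # channel-average -> (windows, bins)
    power_db = 10.0 * np.log10(np.maximum(power, 10.0 ** (DB_FLOOR / 10.0)))
    return power_db, times, freqs


def class_contrast_report(
    dataset: DomainDataset,
    band: tuple[float, float],
    apen_params: ApEnParams = ApEnParams(),
    max_clips_per_class: int = 50,
) -> dict:
    """Per-class mean ApEn and in-band power (dB) — the QC summary showing
    whether seizure clips are separable from background in this dataset.

    Statistics are computed per subject and then averaged, so that subject
    amplitude differences do not masquerade as (or mask) class contrast.
    """
    rate = dataset.sampling_rate
    per_subject: dict[int, dict[str, list]] = {0: {"apen": [], "db": []},
                                               1: {"apen": [], "db": []}}
    counts = {0: 0, 1: 0}
    for sid in dataset.subjects:
        for cls in (0, 1):
            trials = [t for t in dataset.subject_trials(sid)
                      if t.label == cls][:max_clips_per_class]
            if not trials:
                continue
            apens, powers = [], []
            for t in trials:
                apens.append(np.mean([
                    approximate_entropy(ch, apen_params) for ch in t.signal
                ]))
                spec = np.abs(np.fft.rfft(t.signal.astype(np.float64), axis=1)) ** 2
                fr = np.fft.rfftfreq(t.n_samples, d=1.0 / rate)
                sel = (fr >= band[0]) & (fr <= band[1])
                powers.append(10.0 * np.log10(max(spec[:, sel].mean(), 1e-12)))
            per_subject[cls]["apen"].append(float(np.mean(apens)))
            per_subject[cls]["db"].append(float(np.mean(powers)))
            counts[cls] += len(trials)
    out: dict = {"band": band, "classes": {}}
    for cls in (0, 1):
        if per_subject[cls]["db"]:
            out["classes"][cls] = {
                "n": counts[cls],
                "mean_apen": float(np.mean(per_subject[cls]["apen"])),
                "mean_band_power_db": float(np.mean(per_subject[cls]["db"])),
            }
    if 0 in out["classes"] and 1 in out["classes"]:
        out["band_power_contrast_db"] = (
            out["classes"][1]["mean_band_power_db"]
            - out["classes"][0]["mean_band_power_db"]
        )
    return out
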