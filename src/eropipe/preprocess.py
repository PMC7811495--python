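"""Wavelet band filtering, epoch rejection, baseline correction, averaging,
and resampling of epoched ERP data."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from . import dwt
from .dataset import ErpDataset

__all__ = [
    "WaveletFilterSpec",
    "wavelet_filter",
    "reject_epochs",
    "baseline_correct",
    "average_trials",
    "resample",
    "AllTrialsRejectedError",
]


class AllTrialsRejectedError(RuntimeError):
    pass


@dataclass(frozen=True)
class WaveletFilterSpec:
    """Multilevel DWT filter: reconstruct from selected detail levels only.

    Level ``j`` details cover roughly ``fs/2^(j+1) .. fs/2^j`` Hz; the
    defaults (levels 4–8 of rbio6.8) pass ≈ 0.3–9.4 Hz at fs = 150 Hz.
    """

    mother: str = "rbio6.8"
    n_levels: int = 8
    keep_detail_levels: frozenset[int] = frozenset({4, 5, 6, 7, 8})
    keep_approximation: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "keep_detail_levels", frozenset(self.keep_detail_levels))
        bad = [j for j in self.keep_detail_levels if not 1 <= j <= self.n_levels]
        if bad:
            raise ValueError(f"detail levels {bad} outside 1..{self.n_levels}")


def _filter_trace(x: np.ndarray, spec: WaveletFilterSpec) -> np.ndarray:
    coeffs = dwt.wavedec(x, spec.mother, spec.n_levels)
    # coeffs = [cA_n, cD_n, cD_{n-1}, ..., cD_1]
    kept = []
    for k, c in enumerate(coeffs):
        if k == 0:
            keep = spec.keep_approximation
        else:
            level = spec.n_levels - (k - 1)
            keep = level in spec.keep_detail_levels
        kept.append(c if keep else np.zeros_like(c))
    return dwt.waverec(kept, spec.mother, length=len(x))


def wavelet_filter(data, spec: WaveletFilterSpec | None = None):
    """Band-filter a 1-D signal, array, or :class:`ErpDataset`.

    For arrays the last axis is time; each trace is filtered independently.
    """
    spec = spec or WaveletFilterSpec()
    if isinstance(data, ErpDataset):
        return data.with_data(wavelet_filter(data.data, spec))
    x = np.asarray(data, dtype=float)
    if x.ndim == 1:
        if len(x) < 2:
            raise ValueError("signal too short to filter")
        return _filter_trace(x, spec)
    flat = x.reshape(-1, x.shape[-1])
    out = np.empty_like(flat)
    for i, trace in enumerate(flat):
        out[i] = _filter_trace(trace, spec)
    return out.reshape(x.shape)


def reject_epochs(trials: np.ndarray, threshold_uv: float = 100.0,
                  label: str = "") -> tuple[np.ndarray, float]:
    """Keep trials whose absolute amplitude never exceeds the threshold.

    The comparison is inclusive: a trial peaking at exactly ``threshold_uv``
    is kept.  Returns (sorted kept indices, rejected fraction).
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    trials = np.asarray(trials)
    peaks = np.max(np.abs(trials), axis=tuple(range(1, trials.ndim)))
    kept = np.flatnonzero(peaks <= threshold_uv)
    if kept.size == 0:
        where = f" ({label})" if label else ""
        raise AllTrialsRejectedError(f"all {len(trials)} trials rejected{where}")
    return kept, 1.0 - kept.size / len(trials)


def baseline_correct(data: ErpDataset, window: tuple[float, float] = (-200.0, 0.0)) -> ErpDataset:
    """Subtract the per-trace mean over the baseline window."""
    mask = data.time_mask(window)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    return data.with_data(data.data - data.data[..., mask].mean(axis=-1, keepdims=True))


def average_trials(trials: np.ndarray) -> np.ndarray:
    """Arithmetic mean across the leading (trial) axis."""
    trials = np.asarray(trials, dtype=float)
    if len(trials) < 1:
        raise ValueError("no trials to average")
    return trials.mean(axis=0)


def resample(data: ErpDataset, new_srate: float) -> ErpDataset:
    """Polyphase resampling (anti-aliased) to ``new_srate``; rescales times."""
    if new_srate <= 0:
        raise ValueError("new_srate must be positive")
    from fractions import Fraction

    frac = Fraction(new_srate / data.srate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = sps.resample_poly(data.data, up, down, axis=-1)
    n_new = out.shape[-1]
    new_times = data.times[0] + np.arange(n_new) * 1000.0 / new_srate
    return replace(data, data=out, times=new_times, srate=new_srate)
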