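"""Synthetic multi-subject ERP generator with known sources.

Each source is a fixed temporal waveform paired with a fixed scalp
topography; subjects differ only through latency/amplitude jitter applied
to designated sources and through additive white Gaussian noise at a
prescribed SNR.  The noise-free per-source contributions are kept as a
truth side-channel so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import ErpDataset
from .layout import CHANNELS_65, topography_gaussian

__all__ = [
    "SourceSpec",
    "SourceModel",
    "SimulationResult",
    "make_default_sources",
    "simulate_dataset",
    "measured_snr",
]


@dataclass
class SourceSpec:
    """One latent ERP source: unit-peak waveform ⊗ unit-max topography.

    ``amplitude`` (μV) and ``polarity`` (±1) scale the outer product; the
    waveform itself is non-negative with max 1 and vanishes for t < 0.
    """

    name: str
    waveform: np.ndarray
    peak_window: tuple[float, float]
    polarity: int
    topography: np.ndarray
    peak_channel: str
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        self.topography = np.asarray(self.topography, dtype=float)
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be ±1")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass
class SourceModel:
    """Full generative description of a synthetic multi-subject experiment."""

    sources: list[SourceSpec]
    n_channels: int = 65
    srate: float = 150.0
    epoch_window: tuple[float, float] = (-200.0, 800.0)
    channel_labels: list[str] = field(default_factory=lambda: list(CHANNELS_65))
    jittered_sources: frozenset[str] = frozenset({"N2", "P3"})
    latency_jitter_sd: float = 20.0
    amplitude_jitter_sd: float = 0.1
    snr_db: float | None = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must equal n_channels")
        self.jittered_sources = frozenset(self.jittered_sources)

    @property
    def times(self) -> np.ndarray:
        start, end = self.epoch_window
        n = int(round((end - start) / 1000.0 * self.srate)) + 1
        return start + np.arange(n) * 1000.0 / self.srate

    @property
    def n_times(self) -> int:
        return len(self.times)


@dataclass
class SimulationResult:
    """Noisy dataset plus exact noise-free truth, per source and summed."""

    dataset: ErpDataset
    truth: dict[str, ErpDataset]          # per-source noise-free contributions
    truth_total: ErpDataset               # sum over sources
    noise: np.ndarray                     # the additive noise actually drawn
    model: SourceModel


def _hann_lobe(times: np.ndarray, start: float, end: float) -> np.ndarray:
    """Unit-peak raised-cosine pulse supported on [start, end] ms."""
    w = np.zeros_like(times)
    inside = (times >= start) & (times <= end)
    phase = (times[inside] - start) / (end - start)
    w[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    if w.max() > 0:
        w /= w.max()   # exactly unit peak on this grid
    return w


def make_default_sources(seed: int = 0, snr_db: float | None = 10.0,
                         latency_jitter_sd: float = 10.0,
                         amplitude_jitter_sd: float = 0.1,
                         topography_sigma: float = 0.2) -> SourceModel:
    """Four canonical sources (N1, P2, N2, P3) on the default 65-channel grid.

    Peak channels Fz / CPz / FCz / Cz; N2 and P3 carry the between-subject
    jitter.  The P3 pulse is broad (≈ 2.8 Hz) and large so its
    low-frequency power dominates the mixture and masks the weaker N2
    theta activity at fronto-central sites; N2 and P3 supports do not
    overlap so each has a distinct temporal signature.
    """
    model = SourceModel(sources=[], seed=seed, snr_db=snr_db,
                        latency_jitter_sd=latency_jitter_sd,
                        amplitude_jitter_sd=amplitude_jitter_sd)
    t = model.times
    defs = [
        # name, support (ms), polarity, peak channel, amplitude (μV)
        ("N1", (60.0, 160.0), -1, "Fz", 3.0),
        ("P2", (150.0, 270.0), +1, "CPz", 4.0),
        ("N2", (265.0, 385.0), -1, "FCz", 3.5),
        ("P3", (395.0, 575.0), +1, "Cz", 8.0),
    ]
    sources = []
    for name, support, pol, peak_ch, amp in defs:
        sources.append(SourceSpec(
            name=name,
            waveform=_hann_lobe(t, *support),
            peak_window=support,
            polarity=pol,
            topography=topography_gaussian(peak_ch, model.channel_labels,
                                           sigma=topography_sigma),
            peak_channel=peak_ch,
            amplitude=amp,
        ))
    model.sources = sources
    return model


def _shift_waveform(w: np.ndarray, times: np.ndarray, delta_ms: float) -> np.ndarray:
    """Evaluate w(t − delta) on the same grid, zero outside the epoch."""
    return np.interp(times - delta_ms, times, w, left=0.0, right=0.0)


def _positive_scale(rng: np.random.Generator, sd: float, floor: float = 0.1) -> float:
    for _ in range(100):
        s = rng.normal(1.0, sd)
        if s >= floor:
            return float(s)
    return floor


def simulate_dataset(model: SourceModel, n_subjects: int) -> SimulationResult:
    """Draw ``n_subjects`` jittered mixtures of the model's sources.

    Noise variance per subject is set from the post-stimulus mean squared
    mixed signal so that 10·log10(P_signal/P_noise) equals ``model.snr_db``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not model.sources:
        raise ValueError("model has no sources")
    rng = np.random.default_rng(model.seed)
    times = model.times
    nt, nch = model.n_times, model.n_channels
    post = times >= 0.0

    per_source = {s.name: np.zeros((n_subjects, 1, nch, nt)) for s in model.sources}
    data = np.zeros((n_subjects, 1, nch, nt))
    noise = np.zeros_like(data)

    for i in range(n_subjects):
        for src in model.sources:
            w = src.waveform
            scale = 1.0
            if src.name in model.jittered_sources:
                if model.latency_jitter_sd > 0:
                    w = _shift_waveform(w, times, rng.normal(0.0, model.latency_jitter_sd))
                if model.amplitude_jitter_sd > 0:
                    scale = _positive_scale(rng, model.amplitude_jitter_sd)
            contrib = (src.amplitude * src.polarity * scale) * np.outer(src.topography, w)
            per_source[src.name][i, 0] = contrib
        data[i, 0] = sum(per_source[name][i, 0] for name in per_source)
        if model.snr_db is not None:
            p_signal = np.mean(data[i, 0][:, post] ** 2)
            if p_signal <= 0:
                raise ValueError("signal power is zero; cannot set SNR")
            sigma = np.sqrt(p_signal / 10.0 ** (model.snr_db / 10.0))
            noise[i, 0] = rng.normal(0.0, sigma, size=(nch, nt))

    axes = dict(times=times, srate=model.srate,
                channel_labels=list(model.channel_labels),
                condition_labels=["cond1"])
    dataset = ErpDataset(data=data + noise, **axes)
    truth = {name: ErpDataset(data=arr, **axes) for name, arr in per_source.items()}
    truth_total = ErpDataset(data=data, **axes)
    return SimulationResult(dataset=dataset, truth=truth, truth_total=truth_total,
                            noise=noise, model=model)


def measured_snr(noisy: ErpDataset, truth: ErpDataset, per_subject: bool = False):
    """Empirical SNR in dB over post-stimulus samples.

    Returns ``+inf`` when the residual is exactly zero and raises if the
    truth carries no post-stimulus power.
    """
    if noisy.data.shape != truth.data.shape:
        raise ValueError("shape mismatch between noisy data and truth")
    post = truth.times >= 0.0
    axes = (1, 2, 3) if per_subject else None
    s = np.sum(truth.data[..., post] ** 2, axis=axes)
    r = np.sum((noisy.data[..., post] - truth.data[..., post]) ** 2, axis=axes)
    if np.any(np.asarray(s) == 0):
        raise ValueError("truth has zero post-stimulus power; SNR undefined")
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(s / r)
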