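"""Complex Morlet time-frequency power with baseline subtraction, and the
TFA-PCA comparator (PCA + Varimax on flattened TFR surfaces, loading-weighted
back-multiplication)."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

from .dataset import ErpDataset
from .decompose import varimax

__all__ = ["MorletSpec", "TfrSet", "morlet_tfr", "tfa_pca", "TfaPcaResult",
           "build_tfr_matrix", "weight_tfrs"]


@dataclass(frozen=True)
class MorletSpec:
    """Mother-wavelet and frequency-grid description.

    The daughter at analysed frequency f is
    ``(π·fb)^(−1/2) · exp(2πi·fc·t/s) · exp(−t²/(fb·s²))`` with scale
    ``s = fc/f`` (t in seconds), L2-normalized before convolution.  With
    fb = fc = 1 the low-frequency daughters span roughly one cycle — a
    deliberately time-sharp, frequency-coarse analysis.
    """

    fb: float = 1.0
    fc: float = 1.0
    fmin: float = 1.0
    fmax: float = 15.0
    n_bins: int = 30
    spacing: str = "log"
    baseline_window: tuple[float, float] = (-200.0, 0.0)
    pad_mode: str = "zero"   # "zero" | "symmetric" signal extension

    def frequencies(self) -> np.ndarray:
        if self.spacing == "log":
            return np.geomspace(self.fmin, self.fmax, self.n_bins)
        if self.spacing == "linear":
            return np.linspace(self.fmin, self.fmax, self.n_bins)
        raise ValueError("spacing must be 'log' or 'linear'")


@dataclass
class TfrSet:
    """Time-frequency power, ``subjects × conditions × channels × freqs × time``."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    srate: float
    channel_labels: list[str]
    condition_labels: list[str]
    subject_ids: list[str]
    baseline_corrected: bool = False
    baseline_window: tuple[float, float] | None = None

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ValueError(f"channel {label!r} not in TFR set") from None

    def mean_image(self, electrodes: list[str], condition: int | None = None,
                   subjects: slice | None = None) -> np.ndarray:
        """Grand-average freq × time image over electrodes (and subjects)."""
        idx = [self.channel_index(e) for e in electrodes]
        img = self.power[:, :, idx].mean(axis=2)       # S, C, F, T
        img = img.mean(axis=0) if subjects is None else img[subjects].mean(axis=0)
        return img.mean(axis=0) if condition is None else img[condition]


def _daughter(f: float, spec: MorletSpec, srate: float) -> np.ndarray:
    s = spec.fc / f                                    # scale, seconds
    sigma_t = s * np.sqrt(spec.fb / 2.0)
    half = int(np.ceil(5.0 * sigma_t * srate))
    t = np.arange(-half, half + 1) / srate
    psi = (np.pi * spec.fb) ** -0.5 \
        * np.exp(2j * np.pi * spec.fc * t / s) \
        * np.exp(-t**2 / (spec.fb * s**2))
    psi /= np.sqrt(np.sum(np.abs(psi) ** 2) / srate)   # unit L2 norm
    return psi


def morlet_tfr(data: ErpDataset, spec: MorletSpec | None = None,
               baseline: bool = True) -> TfrSet:
    """CWT power of every trace; optionally subtract per-frequency mean
    baseline power.  Symmetric signal padding keeps interior values
    independent of the boundary treatment."""
    spec = spec or MorletSpec()
    freqs = spec.frequencies()
    if freqs[-1] >= data.srate / 2.0:
        raise ValueError(f"max frequency {freqs[-1]:.2f} Hz at/above Nyquist")
    cube = data.data
    ns, nc, nch, nt = cube.shape
    flat = cube.reshape(-1, nt)
    power = np.empty((flat.shape[0], len(freqs), nt))
    for k, f in enumerate(freqs):
        kern = _daughter(f, spec, data.srate)
        pad = min(len(kern) // 2, nt - 1)
        if spec.pad_mode == "zero":
            padded = np.pad(flat, ((0, 0), (pad, pad)))
        elif spec.pad_mode == "symmetric":
            padded = np.pad(flat, ((0, 0), (pad, pad)), mode="symmetric")
        else:
            raise ValueError("pad_mode must be 'zero' or 'symmetric'")
        w = fftconvolve(padded, kern[None, :], mode="same", axes=1)
        w = w[:, pad:pad + nt]
        power[:, k] = np.abs(w) ** 2
    power = power.reshape(ns, nc, nch, len(freqs), nt)
    out = TfrSet(
        power=power, freqs=freqs, times=data.times.copy(), srate=data.srate,
        channel_labels=list(data.channel_labels),
        condition_labels=list(data.condition_labels),
        subject_ids=list(data.subject_ids),
    )
    if baseline:
        lo, hi = spec.baseline_window
        mask = (out.times >= lo) & (out.times <= hi)
        if not mask.any():
            raise ValueError("baseline window contains no samples")
        out.power = out.power - out.power[..., mask].mean(axis=-1, keepdims=True)
        out.baseline_corrected = True
        out.baseline_window = spec.baseline_window
    return out


def build_tfr_matrix(tfrs: TfrSet, time_window: tuple[float, float] | None = None):
    """Flatten TFRs to the comparator's observation matrix.

    Rows are cases (subject-major, then condition, then channel); columns
    are frequency-major flattened (freq, time) surfaces over ``time_window``
    (right-open; defaults to t ≥ 0).  Returns (matrix, time mask,
    (n_freqs, n_times)).
    """
    if not tfrs.baseline_corrected:
        raise ValueError("tfa_pca expects baseline-corrected TFRs")
    times = tfrs.times
    if time_window is None:
        tmask = times >= 0.0
    else:
        tmask = (times >= time_window[0]) & (times < time_window[1])
    sub = tfrs.power[..., tmask]                     # S, C, Ch, F, T'
    ns, nc, nch, nf, ntw = sub.shape
    return sub.reshape(ns * nc * nch, nf * ntw), tmask, (nf, ntw)


@dataclass
class TfaPcaResult:
    """PCA+Varimax on flattened TFRs and the loading-weighted TFR sets."""

    eigenvalues: np.ndarray
    explained_variance_pct: np.ndarray
    loadings: np.ndarray                 # (F·T) × R varimax-rotated
    R: int
    weighted: dict[int, TfrSet] = field(default_factory=dict)
    matrix_shape: tuple[int, int] = (0, 0)

    def loading_surface(self, component: int, n_freqs: int) -> np.ndarray:
        return self.loadings[:, component].reshape(n_freqs, -1)


def tfa_pca(tfrs: TfrSet, variance_threshold: float = 0.99,
            components: list[int] | None = None,
            time_window: tuple[float, float] | None = None) -> TfaPcaResult:
    """The comparator: PCA (covariance), Kaiser-normalized Varimax, then each
    selected component's loading surface multiplied elementwise into every
    case's original TFR.

    Rows are cases (subject-major, then condition, then channel); columns are
    frequency-major flattened (freq, time) surfaces over ``time_window``
    (right-open; defaults to t ≥ 0).
    """
    X, tmask, (nf, ntw) = build_tfr_matrix(tfrs, time_window)
    mu = X.mean(axis=0)
    Xc = X - mu
    n = X.shape[0]
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / max(n - 1, 1)
    total = eig.sum()
    expl = eig / total * 100.0
    cum = np.cumsum(eig) / total
    R = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    A = Vt[:R].T * (s[:R] / np.sqrt(max(n - 1, 1)))
    rotated, _ = varimax(A, kaiser=True)
    result = TfaPcaResult(
        eigenvalues=eig,
        explained_variance_pct=expl,
        loadings=rotated,
        R=R,
        matrix_shape=X.shape,
    )
    for j in components or []:
        if not 0 <= j < R:
            raise ValueError(f"component {j} outside retained range 0..{R-1}")
        surface = rotated[:, j].reshape(nf, ntw)
        result.weighted[j] = weight_tfrs(tfrs, surface, tmask)
    return result


def weight_tfrs(tfrs: TfrSet, surface: np.ndarray, tmask: np.ndarray) -> TfrSet:
    """Elementwise product of a freq × time loading surface with every case's
    TFR over the masked time samples (zero outside)."""
    weighted = np.zeros_like(tfrs.power)
    weighted[..., tmask] = tfrs.power[..., tmask] * surface
    return replace(
        tfrs, power=weighted,
        channel_labels=list(tfrs.channel_labels),
        condition_labels=list(tfrs.condition_labels),
        subject_ids=list(tfrs.subject_ids),
    )
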