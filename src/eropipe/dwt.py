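"""Multilevel 1-D discrete wavelet transform with symmetric boundary extension.

Implements the Mallat analysis/synthesis cascade.  Decomposition of a
length-``n`` signal at one level yields coefficient vectors of length
``floor((n + L - 1) / 2)`` where ``L`` is the filter length; the synthesis
step inverts it exactly (perfect reconstruction), including for signals far
shorter than ``L · 2^levels``.
"""

from __future__ import annotations

import numpy as np

from ._filter_banks import get_filter_bank

__all__ = ["dwt", "idwt", "wavedec", "waverec"]


def _symmetric_extend(x: np.ndarray, pad: int) -> np.ndarray:
    """Half-sample symmetric extension: [.. x1 x0 | x0 x1 ..] on both ends."""
    n = len(x)
    if pad <= n:
        return np.concatenate([x[:pad][::-1], x, x[n - pad :][::-1]])
    # Pad wider than the signal: tile reflections.
    period = np.concatenate([x, x[::-1]])
    idx = (np.arange(-pad, n + pad)) % (2 * n)
    return period[idx]


def dwt(x: np.ndarray, wavelet: str = "rbio6.8") -> tuple[np.ndarray, np.ndarray]:
    """Single-level DWT; returns (approximation, detail) coefficients."""
    bank = get_filter_bank(wavelet)
    x = np.asarray(x, dtype=float)
    L = len(bank["dec_lo"])
    n = len(x)
    out_len = (n + L - 1) // 2
    ext = _symmetric_extend(x, L - 1)
    ca = np.convolve(ext, bank["dec_lo"])[L : L + 2 * out_len : 2]
    cd = np.convolve(ext, bank["dec_hi"])[L : L + 2 * out_len : 2]
    return ca, cd


def idwt(ca: np.ndarray, cd: np.ndarray, wavelet: str = "rbio6.8") -> np.ndarray:
    """Single-level inverse DWT.  Output length is ``2·len(ca) − L + 2``."""
    bank = get_filter_bank(wavelet)
    ca = np.asarray(ca, dtype=float)
    cd = np.asarray(cd, dtype=float)
    if len(ca) != len(cd):
        raise ValueError("approximation/detail length mismatch")
    L = len(bank["rec_lo"])
    up_a = np.zeros(2 * len(ca))
    up_a[::2] = ca
    up_d = np.zeros(2 * len(cd))
    up_d[::2] = cd
    full = np.convolve(up_a, bank["rec_lo"]) + np.convolve(up_d, bank["rec_hi"])
    out_len = 2 * len(ca) - L + 2
    if out_len < 1:
        raise ValueError("coefficient vector too short to invert")
    return full[L - 2 : L - 2 + out_len]


def wavedec(x: np.ndarray, wavelet: str = "rbio6.8", level: int = 8) -> list[np.ndarray]:
    """Multilevel decomposition: ``[cA_level, cD_level, ..., cD_1]``."""
    if level < 1:
        raise ValueError("level must be >= 1")
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("signal too short for wavelet decomposition")
    coeffs: list[np.ndarray] = []
    a = x
    for _ in range(level):
        a, d = dwt(a, wavelet)
        coeffs.append(d)
    coeffs.append(a)
    return coeffs[::-1]


def waverec(coeffs: list[np.ndarray], wavelet: str = "rbio6.8", length: int | None = None) -> np.ndarray:
    """Reconstruct from a ``wavedec`` coefficient list.

    ``length`` trims the result to the original signal length (the cascade
    can overshoot by one sample per level for odd intermediate lengths).
    """
    a = np.asarray(coeffs[0], dtype=float)
    for d in coeffs[1:]:
        d = np.asarray(d, dtype=float)
        if len(a) == len(d) + 1:
            a = a[:-1]
        a = idwt(a, d, wavelet)
    if length is not None:
        a = a[:length]
    return a
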