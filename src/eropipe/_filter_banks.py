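"""Quadrature filter banks for the discrete wavelet transform.

Coefficients are stored explicitly so the transform has no runtime
dependency beyond numpy.  Each entry maps a wavelet name to the four
filters (decomposition low/high, reconstruction low/high), all of equal
length, in the convolution orientation used by :mod:`eropipe.dwt`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FILTER_BANKS", "get_filter_bank"]

# Reverse biorthogonal 6.8: the analysis/synthesis roles of the bior6.8
# spline pair are swapped.  18 taps.
_RBIO68_DEC_LO = [
    0.0, 0.0, 0.0, 0.0,
    0.014426282505624435, 0.014467504896790148,
    -0.07872200106262882, -0.04036797903033992,
    0.41784910915027457, 0.7589077294536541,
    0.41784910915027457, -0.04036797903033992,
    -0.07872200106262882, 0.014467504896790148,
    0.014426282505624435, 0.0, 0.0, 0.0,
]
_RBIO68_DEC_HI = [
    -0.0019088317364812906, -0.0019142861290887667,
    0.016990639867602342, 0.01193456527972926,
    -0.04973290349094079, -0.07726317316720414,
    0.09405920349573646, 0.4207962846098268,
    -0.8259229974584023, 0.4207962846098268,
    0.09405920349573646, -0.07726317316720414,
    -0.04973290349094079, 0.01193456527972926,
    0.016990639867602342, -0.0019142861290887667,
    -0.0019088317364812906, 0.0,
]
_RBIO68_REC_LO = [
    0.0019088317364812906, -0.0019142861290887667,
    -0.016990639867602342, 0.01193456527972926,
    0.04973290349094079, -0.07726317316720414,
    -0.09405920349573646, 0.4207962846098268,
    0.8259229974584023, 0.4207962846098268,
    -0.09405920349573646, -0.07726317316720414,
    0.04973290349094079, 0.01193456527972926,
    -0.016990639867602342, -0.0019142861290887667,
    0.0019088317364812906, 0.0,
]
_RBIO68_REC_HI = [
    0.0, -0.0, 0.0, -0.0,
    0.014426282505624435, -0.014467504896790148,
    -0.07872200106262882, 0.04036797903033992,
    0.41784910915027457, -0.7589077294536541,
    0.41784910915027457, 0.04036797903033992,
    -0.07872200106262882, -0.014467504896790148,
    0.014426282505624435, -0.0, 0.0, -0.0,
]

# Daubechies 4, included for configurability tests.  8 taps.
_SQ3 = np.sqrt(3.0)
_D4 = np.array([
    0.23037781330885523, 0.7148465705525415, 0.6308807679295904,
    -0.02798376941698385, -0.18703481171888114, 0.030841381835986965,
    0.032883011666982945, -0.010597401784997278,
])


def _orth_bank(h: np.ndarray) -> dict[str, np.ndarray]:
    """Build the four filters of an orthogonal bank from scaling coeffs ``h``."""
    signs = np.where(np.arange(len(h)) % 2 == 0, -1.0, 1.0)
    dec_hi = h * signs
    return {
        "dec_lo": h[::-1].copy(), "dec_hi": dec_hi,
        "rec_lo": h.copy(), "rec_hi": dec_hi[::-1].copy(),
    }


FILTER_BANKS: dict[str, dict[str, np.ndarray]] = {
    "rbio6.8": {
        "dec_lo": np.asarray(_RBIO68_DEC_LO),
        "dec_hi": np.asarray(_RBIO68_DEC_HI),
        "rec_lo": np.asarray(_RBIO68_REC_LO),
        "rec_hi": np.asarray(_RBIO68_REC_HI),
    },
    "db4": _orth_bank(_D4),
}


def get_filter_bank(name: str) -> dict[str, np.ndarray]:
    """Return the filter bank for ``name``, raising ``ValueError`` if unknown."""
    try:
        return FILTER_BANKS[name]
    except KeyError:
        known = ", ".join(sorted(FILTER_BANKS))
        raise ValueError(f"unknown mother wavelet {name!r}; known: {known}") from None
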