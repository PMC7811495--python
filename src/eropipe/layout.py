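"""A 65-channel 10-20/10-10 scalp layout with schematic 2-D positions.

Positions are on a unit-ish disc (x: left−/right+, y: front+/back−) and are
used only to shape smooth spatial topographies; no forward modelling.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CHANNELS_65", "channel_positions", "topography_gaussian"]

_ROWS: list[tuple[str, float, list[str]]] = [
    ("Fp", 0.80, ["Fp1", "Fpz", "Fp2"]),
    ("AF", 0.62, ["AF7", "AF3", "AFz", "AF4", "AF8"]),
    ("F", 0.44, ["F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8"]),
    ("FC", 0.22, ["FT9", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10"]),
    ("C", 0.00, ["T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8"]),
    ("CP", -0.22, ["TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10"]),
    ("P", -0.44, ["P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8"]),
    ("PO", -0.62, ["PO7", "PO3", "POz", "PO4", "PO8"]),
    ("O", -0.80, ["O1", "Oz", "O2"]),
]

# lateral index (label digit) -> |x|; odd digits are left hemisphere
_XPOS = {0: 0.0, 1: 0.12, 2: 0.12, 3: 0.28, 4: 0.28, 5: 0.44, 6: 0.44,
         7: 0.62, 8: 0.62, 9: 0.80, 10: 0.80}


def _label_x(label: str) -> float:
    if label.endswith("z"):
        return 0.0
    digits = "".join(ch for ch in label if ch.isdigit())
    d = int(digits)
    mag = _XPOS[d]
    return -mag if d % 2 == 1 else mag


def _build() -> tuple[list[str], np.ndarray]:
    names: list[str] = []
    pos: list[tuple[float, float]] = []
    for _, y, labels in _ROWS:
        for lab in labels:
            names.append(lab)
            pos.append((_label_x(lab), y))
    return names, np.asarray(pos)


CHANNELS_65, _POS_65 = _build()
assert len(CHANNELS_65) == 65


def channel_positions(channels: list[str] | None = None) -> np.ndarray:
    """Return (n, 2) x/y positions for the given channel labels."""
    if channels is None:
        return _POS_65.copy()
    lookup = {c: p for c, p in zip(CHANNELS_65, _POS_65)}
    try:
        return np.asarray([lookup[c] for c in channels])
    except KeyError as exc:
        raise ValueError(f"unknown channel label {exc.args[0]!r}") from None


def topography_gaussian(peak_channel: str, channels: list[str] | None = None,
                        sigma: float = 0.35) -> np.ndarray:
    """Unit-max spatial Gaussian centred on ``peak_channel``."""
    chans = channels if channels is not None else CHANNELS_65
    pos = channel_positions(chans)
    centre = channel_positions([peak_channel])[0]
    d2 = np.sum((pos - centre) ** 2, axis=1)
    topo = np.exp(-d2 / (2.0 * sigma**2))
    return topo / topo.max()
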