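"""Container for epoched / averaged ERP voltage data and its axes."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ErpDataset"]


@dataclass
class ErpDataset:
    """Averaged ERP data, ``subjects × conditions × channels × time`` (μV).

    ``times`` is in milliseconds, strictly increasing and uniform at
    ``1000/srate``.
    """

    data: np.ndarray
    times: np.ndarray
    srate: float
    channel_labels: list[str]
    condition_labels: list[str] = field(default_factory=lambda: ["cond1"])
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (subjects, conditions, channels, time)")
        ns, nc, nch, nt = self.data.shape
        if not self.subject_ids:
            self.subject_ids = [f"S{i+1:02d}" for i in range(ns)]
        if nc != len(self.condition_labels):
            raise ValueError("condition axis does not match condition_labels")
        if nch != len(self.channel_labels):
            raise ValueError("channel axis does not match channel_labels")
        if nt != len(self.times):
            raise ValueError("time axis does not match times")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, 1000.0 / self.srate, rtol=1e-6)):
            raise ValueError("times must be uniform at 1000/srate ms and increasing")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def n_times(self) -> int:
        return self.data.shape[3]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ValueError(f"channel {label!r} not in dataset") from None

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean mask over the time axis, inclusive on both ends."""
        lo, hi = window
        if lo > hi:
            raise ValueError("window start exceeds end")
        return (self.times >= lo) & (self.times <= hi)

    def with_data(self, data: np.ndarray) -> "ErpDataset":
        return replace(self, data=np.asarray(data, dtype=float))
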