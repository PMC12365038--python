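"""Shared in-memory containers for sensor-space data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class RawRecording:
    """Continuous multichannel field recording.

    data is (n_channels, n_samples) in tesla; each channel carries a position
    (m, head-centred), a unit measurement-axis vector and a bad flag.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    positions: np.ndarray       # (n_channels, 3)
    axes: np.ndarray            # (n_channels, 3), unit norm
    bad: np.ndarray = None      # (n_channels,) bool
    events: pd.DataFrame | None = None
    hfc_applied: bool = False   # uniform-field projector already applied
    validate: bool = True       # False skips the O(data) finiteness scan

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.validate and not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        self.positions = np.asarray(self.positions, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        norms = np.linalg.norm(self.axes, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-10):
            raise ValueError("axis vectors must be unit norm")
        if self.bad is None:
            self.bad = np.zeros(self.n_channels, dtype=bool)
        self.bad = np.asarray(self.bad, dtype=bool)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def good(self) -> np.ndarray:
        return ~self.bad

    def copy_with(self, **kw) -> "RawRecording":
        """Shallow-copy variant; derived data are trusted (no finiteness rescan)."""
        base = dict(data=self.data, fs=self.fs, channel_names=list(self.channel_names),
                    positions=self.positions, axes=self.axes, bad=self.bad.copy(),
                    events=self.events, hfc_applied=self.hfc_applied,
                    validate=False)
        base.update(kw)
        return RawRecording(**base)
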