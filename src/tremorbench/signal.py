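"""Uniformly sampled multi-channel time series plus small spectral helpers.

:class:`SignalTrace` is the unit every simulation and DSP stage consumes and
produces: a strictly uniform time grid at sampling rate ``fs`` and one or
more named real-valued channels of equal length (e.g. ``force_x`` /
``force_y`` from a haptic device's built-in force sensors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import periodogram

__all__ = ["SignalTrace", "band_power", "band_rms"]

#: maximum deviation of the time grid from 1/fs, in seconds
_GRID_TOL = 1e-9


@dataclass
class SignalTrace:
    """Multi-channel time series on a uniform grid.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz, > 0.
    t : numpy.ndarray
        Sample times in seconds; strictly increasing with spacing 1/fs.
    channels : dict[str, numpy.ndarray]
        Named channels, each the same length as ``t``.
    """

    fs: float
    t: np.ndarray
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1:
            raise ValueError("t must be one-dimensional")
        if self.t.size > 1:
            dt = np.diff(self.t)
            if np.any(np.abs(dt - 1.0 / self.fs) > _GRID_TOL):
                raise ValueError("t is not a uniform grid at 1/fs spacing")
        clean: dict[str, np.ndarray] = {}
        for name, x in self.channels.items():
            x = np.asarray(x, dtype=float)
            if x.shape != self.t.shape:
                raise ValueError(
                    f"channel {name!r} has length {x.size}, expected {self.t.size}"
                )
            clean[name] = x
        self.channels = clean

    # -- construction ----------------------------------------------------
    @classmethod
    def from_arrays(
        cls, fs: float, channels: dict[str, np.ndarray], t0: float = 0.0
    ) -> "SignalTrace":
        """Build a trace from channel arrays, synthesising the time grid."""
        n = len(next(iter(channels.values()))) if channels else 0
        t = t0 + np.arange(n) / fs
        return cls(fs=fs, t=t, channels=channels)

    # -- basic properties ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def copy_with(self, channels: dict[str, np.ndarray]) -> "SignalTrace":
        """Same grid, new channel data."""
        return SignalTrace(fs=self.fs, t=self.t.copy(), channels=channels)

    def __add__(self, other: "SignalTrace") -> "SignalTrace":
        if set(self.channels) != set(other.channels):
            raise ValueError("channel sets differ")
        return self.copy_with(
            {k: self.channels[k] + other.channels[k] for k in self.channels}
        )

    # -- I/O --------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.t})
        for name, x in self.channels.items():
            df[name] = x
        return df

    def to_csv(self, path) -> None:
        """Write ``time,<channel>...`` CSV, one row per sample."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fs: float | None = None) -> "SignalTrace":
        """Read a ``time,<channel>...`` CSV; ``fs`` is inferred from the
        time column when not given."""
        df = pd.read_csv(path)
        if "time" not in df.columns:
            raise ValueError(f"{path}: missing 'time' column")
        t = df["time"].to_numpy(dtype=float)
        if fs is None:
            if t.size < 2:
                raise ValueError(f"{path}: cannot infer fs from {t.size} samples")
            fs = 1.0 / float(np.median(np.diff(t)))
        channels = {
            c: df[c].to_numpy(dtype=float) for c in df.columns if c != "time"
        }
        return cls(fs=fs, t=t, channels=channels)


def band_power(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """Integrated periodogram power of ``x`` over the band [lo, hi] Hz."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0.0
    f, p = periodogram(x, fs=fs)
    mask = (f >= lo) & (f <= hi)
    if not np.any(mask):
        return 0.0
    df = f[1] - f[0]
    return float(np.sum(p[mask]) * df)


def band_rms(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """Root of the band power: RMS amplitude of the band-limited content."""
    return float(np.sqrt(band_power(x, fs, lo, hi)))
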