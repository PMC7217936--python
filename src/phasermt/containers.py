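"""Shared in-memory containers for recordings and epochs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Laplacian montage neighbourhoods of the 10-20 system used for the
#: sensorimotor hand areas: centre electrode minus the mean of the four
#: surrounding electrodes.
LAPLACIAN_NEIGHBORS: dict[str, tuple[str, str, str, str]] = {
    "C3": ("FC1", "FC5", "CP1", "CP5"),
    "C4": ("FC2", "FC6", "CP2", "CP6"),
}

#: Default EEG montage (both sensorimotor Laplacian sets).
DEFAULT_MONTAGE: tuple[str, ...] = (
    "C3", "C4", "FC1", "FC2", "FC5", "FC6", "CP1", "CP2", "CP5", "CP6",
)


@dataclass
class Recording:
    """Multichannel raw time series.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channels : tuple of str
        Channel labels, one per row of ``data``.
    ground_truth : dict or None
        For synthetic recordings: ``mu_freq`` (Hz), ``phi0`` (rad),
        ``amp`` (uV, source amplitude), ``center`` (label).  Allows the
        analytic phase of the injected mu component to be recovered
        exactly at any sample.
    """

    data: np.ndarray
    fs: float
    channels: tuple[str, ...]
    ground_truth: dict | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError("number of channel labels must match data rows")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channels.index(label) if isinstance(self.channels, list) \
                else list(self.channels).index(label)
        except ValueError as err:
            raise KeyError(f"channel {label!r} not in recording") from err
        return self.data[idx]

    def true_phase(self, samples) -> np.ndarray | float:
        """Analytic phase of the injected mu component at given sample(s).

        Phase convention: 0 rad at the signal's positive peak, +/-pi at
        the negative peak.  Only available for synthetic recordings.
        """
        if self.ground_truth is None:
            raise ValueError("recording has no ground-truth mu component")
        t = np.asarray(samples, dtype=float) / self.fs
        phi = 2.0 * np.pi * self.ground_truth["mu_freq"] * t + self.ground_truth["phi0"]
        return wrap_phase(phi)


def wrap_phase(phi):
    """Wrap angle(s) to [-pi, pi)."""
    return np.mod(np.asarray(phi) + np.pi, 2.0 * np.pi) - np.pi


def circ_distance(a, b):
    """Absolute circular distance between angles, in [0, pi]."""
    return np.abs(wrap_phase(np.asarray(a) - np.asarray(b)))


@dataclass
class Epoch:
    """One channel's samples around a TMS pulse (pulse at 0 ms)."""

    samples: np.ndarray
    fs: float
    t0_offset_ms: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def index_of(self, t_ms: float) -> int:
        """Sample index of time ``t_ms`` relative to the pulse."""
        return int(round((t_ms - self.t0_offset_ms) * self.fs / 1000.0))

    def window(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Samples in [start_ms, stop_ms] (inclusive); raises if uncovered."""
        i0, i1 = self.index_of(start_ms), self.index_of(stop_ms)
        if i0 < 0 or i1 > len(self.samples) - 1:
            raise ValueError(
                f"epoch does not cover [{start_ms}, {stop_ms}] ms"
            )
        return self.samples[i0 : i1 + 1]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_offset_ms + np.arange(len(self.samples)) * 1000.0 / self.fs
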