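"""Time-frequency sampling grid shared by every pipeline stage.

A biodynamic assay cycles through all wells of a plate once per *loop*
(82 min by default), producing one fluctuation power spectrum per well per
loop.  The spectra live on a log-spaced frequency axis bounded below by the
slowest resolvable motions (10 mHz) and above by the camera Nyquist
frequency (12.5 Hz at 25 frames per second).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TimeFrequencyGrid", "nyquist_frequency"]


def nyquist_frequency(frame_rate_hz: float) -> float:
    """Nyquist frequency (Hz) of an intensity time series sampled at ``frame_rate_hz``."""
    if frame_rate_hz <= 0:
        raise ValueError("frame rate must be positive")
    return frame_rate_hz / 2.0


@dataclass(frozen=True)
class TimeFrequencyGrid:
    """Shared loop-time x Doppler-frequency grid.

    Parameters
    ----------
    frequencies:
        Strictly increasing frequency samples in Hz (log-spaced by default,
        50 points from 10 mHz to the 12.5 Hz Nyquist frequency).
    loop_times:
        Strictly increasing loop start times in hours, uniformly spaced by
        ``loop_period`` minutes.
    dose_loop:
        Number of pre-dose (baseline) loops; the drug is dispensed after
        loop ``dose_loop - 1``, so loops ``0 .. dose_loop-1`` are baseline
        and the remaining loops are post-dose.
    loop_period:
        Loop duration in minutes (time to cycle through all wells once).
    """

    frequencies: np.ndarray
    loop_times: np.ndarray
    dose_loop: int = 4
    loop_period: float = 82.0

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        times = np.asarray(self.loop_times, dtype=float)
        object.__setattr__(self, "frequencies", freqs)
        object.__setattr__(self, "loop_times", times)
        if freqs.ndim != 1 or freqs.size < 2:
            raise ValueError("frequencies must be a 1-D array with >= 2 samples")
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if freqs[0] <= 0:
            raise ValueError("frequencies must be positive")
        if times.ndim != 1 or np.any(np.diff(times) <= 0):
            raise ValueError("loop_times must be strictly increasing")
        if not 0 < self.dose_loop < times.size:
            raise ValueError("dose_loop must leave at least one loop on each side of the dose")
        spacing_h = np.diff(times)
        if not np.allclose(spacing_h, self.loop_period / 60.0, rtol=1e-6):
            raise ValueError("loop_times spacing must equal loop_period")

    @classmethod
    def default(
        cls,
        n_frequencies: int = 50,
        f_min: float = 0.01,
        f_max: float = 12.5,
        n_pre_loops: int = 4,
        n_post_loops: int = 9,
        loop_period_min: float = 82.0,
    ) -> "TimeFrequencyGrid":
        """Build the standard assay grid: 50 log-spaced frequencies from
        10 mHz to 12.5 Hz, 4 baseline + 9 post-dose loops of 82 min
        (5.5 h baseline followed by 12.3 h of drug response)."""
        freqs = np.geomspace(f_min, f_max, n_frequencies)
        n_loops = n_pre_loops + n_post_loops
        times = np.arange(n_loops) * loop_period_min / 60.0
        return cls(frequencies=freqs, loop_times=times, dose_loop=n_pre_loops,
                   loop_period=loop_period_min)

    # -- derived quantities -------------------------------------------------

    @property
    def n_frequencies(self) -> int:
        return int(self.frequencies.size)

    @property
    def n_loops(self) -> int:
        return int(self.loop_times.size)

    @property
    def n_pre_loops(self) -> int:
        return int(self.dose_loop)

    @property
    def n_post_loops(self) -> int:
        return self.n_loops - self.dose_loop

    @property
    def post_loop_indices(self) -> np.ndarray:
        return np.arange(self.dose_loop, self.n_loops)

    @property
    def post_loop_times(self) -> np.ndarray:
        return self.loop_times[self.dose_loop:]

    @property
    def nyquist(self) -> float:
        return float(self.frequencies[-1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimeFrequencyGrid):
            return NotImplemented
        return (
            np.array_equal(self.frequencies, other.frequencies)
            and np.array_equal(self.loop_times, other.loop_times)
            and self.dose_loop == other.dose_loop
            and self.loop_period == other.loop_period
        )
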