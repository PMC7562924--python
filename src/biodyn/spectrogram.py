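"""Drug-response spectrograms from per-well fluctuation spectra.

The drug-response spectrogram is the log-ratio of the post-dose spectral
density to the pre-dose baseline,

    D(omega, t) = log10 S(omega, t) - log10 S(omega, 0),

where the baseline S(omega, 0) is the geometric mean of the last four
pre-dose loops.  Replicate wells are combined by a data-quality-weighted
average, and the vehicle (DMSO) control spectrogram is subtracted before
biomarker extraction.

Data quality (DQ) starts at unity and is halved for every violated
quality-control criterion; the two measurable criteria are a sudden jump
in well brightness (immobilization shift) and low cell activity, and any
pre-assigned violation flags also count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .grid import TimeFrequencyGrid
from .synthetic import WellRecord

__all__ = [
    "FluctuationSpectrumSeries",
    "DrugResponseSpectrogram",
    "DQThresholds",
    "power_spectrum",
    "baseline_average",
    "drug_response_spectrogram",
    "assess_data_quality",
    "activity_band_power",
    "cohort_activity_threshold",
    "weighted_average_spectrograms",
    "subtract_control",
]


@dataclass
class FluctuationSpectrumSeries:
    """Per-well series of fluctuation power spectra, one per loop."""

    grid: TimeFrequencyGrid
    spectra: np.ndarray  # [n_loops, n_frequencies], strictly positive
    brightness: np.ndarray | None = None
    violations: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.shape != (self.grid.n_loops, self.grid.n_frequencies):
            raise ValueError("spectra shape must be [n_loops, n_frequencies]")
        if np.any(self.spectra <= 0):
            raise ValueError("spectral densities must be strictly positive")

    @classmethod
    def from_well(cls, well: WellRecord, grid: TimeFrequencyGrid) -> "FluctuationSpectrumSeries":
        return cls(grid=grid, spectra=well.spectra, brightness=well.brightness,
                   violations=list(well.violations))


@dataclass
class DrugResponseSpectrogram:
    """Baseline-referenced log10 spectrogram over the post-dose loops.

    ``dq`` is 2**(-m) for a single well; a replicate-averaged spectrogram
    stores the mean of the input DQs instead.
    """

    grid: TimeFrequencyGrid
    D: np.ndarray  # [n_post_loops, n_frequencies]
    treatment: str
    dq: float = 1.0
    baseline: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.shape != (self.grid.n_post_loops, self.grid.n_frequencies):
            raise ValueError("D shape must be [n_post_loops, n_frequencies]")
        if not np.all(np.isfinite(self.D)):
            raise ValueError("spectrogram must be finite")
        if not 0 < self.dq <= 1:
            raise ValueError("DQ must lie in (0, 1]")

    def band_mean(self, f_lo: float, f_hi: float) -> float:
        """Mean of D over frequencies in [f_lo, f_hi) and all post-dose loops."""
        sel = (self.grid.frequencies >= f_lo) & (self.grid.frequencies < f_hi)
        if not np.any(sel):
            raise ValueError("band contains no grid frequencies")
        return float(self.D[:, sel].mean())


# ---------------------------------------------------------------------------
# spectrum estimation


def power_spectrum(
    series: np.ndarray, frame_rate: float, grid: TimeFrequencyGrid
) -> np.ndarray:
    """One-sided power spectral density of an intensity time series,
    resampled onto the log-frequency grid.

    The periodogram is computed at the camera frame rate (25 fps by
    default elsewhere) after mean removal, so its integral recovers the
    series variance (Parseval).  Resampling averages the linear-frequency
    periodogram inside each log-grid bin, which preserves band-integrated
    power on the display grid; bins narrower than the frequency resolution
    are filled by log-log interpolation.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("intensity series must contain at least 2 samples")
    freqs, psd = signal.periodogram(x, fs=frame_rate, detrend="constant",
                                    window="boxcar", scaling="density")
    # drop the DC bin; log grid starts at a strictly positive frequency
    freqs, psd = freqs[1:], psd[1:]

    gf = grid.frequencies
    edges = np.empty(gf.size + 1)
    edges[1:-1] = np.sqrt(gf[:-1] * gf[1:])  # geometric midpoints
    edges[0] = gf[0] ** 2 / edges[1]
    edges[-1] = gf[-1] ** 2 / edges[-2]

    out = np.full(gf.size, np.nan)
    idx = np.searchsorted(edges, freqs, side="right") - 1
    for k in range(gf.size):
        sel = idx == k
        if np.any(sel):
            out[k] = psd[sel].mean()
    empty = np.isnan(out)
    if np.all(empty):
        raise ValueError("no periodogram frequencies fall on the grid")
    if np.any(empty):
        # log-log interpolation into unresolved low-frequency bins
        pos = psd > 0
        fill = np.interp(np.log(gf[empty]), np.log(freqs[pos]),
                         np.log(np.maximum(psd[pos], 1e-300)))
        out[empty] = np.exp(fill)
    return out


# ---------------------------------------------------------------------------
# baseline and spectrogram


def baseline_average(series: FluctuationSpectrumSeries) -> np.ndarray:
    """Baseline spectrum S(omega, 0): per-frequency geometric mean of the
    last four pre-dose loops."""
    n_pre = series.grid.n_pre_loops
    if n_pre < 4:
        raise ValueError("baseline requires at least 4 pre-dose loops")
    pre = series.spectra[n_pre - 4: n_pre]
    return 10.0 ** np.log10(pre).mean(axis=0)


def drug_response_spectrogram(
    series: FluctuationSpectrumSeries,
    baseline: np.ndarray | None = None,
    treatment: str = "unknown",
    dq: float = 1.0,
) -> DrugResponseSpectrogram:
    """D(omega, t) = log10 S(omega, t) - log10 S(omega, 0) over post-dose loops."""
    if baseline is None:
        baseline = baseline_average(series)
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != (series.grid.n_frequencies,):
        raise ValueError("baseline length must match the frequency grid")
    if np.any(baseline <= 0):
        raise ValueError("baseline spectral density must be strictly positive")
    post = series.spectra[series.grid.dose_loop:]
    D = np.log10(post) - np.log10(baseline)
    return DrugResponseSpectrogram(grid=series.grid, D=D, treatment=treatment,
                                   dq=dq, baseline=baseline)


# ---------------------------------------------------------------------------
# data quality


@dataclass(frozen=True)
class DQThresholds:
    """Thresholds for the measurable quality-control criteria.

    brightness_jump_ratio: a consecutive-loop brightness ratio above this
    (or below its inverse) flags an immobilization shift (default x1.5).
    min_band_power: absolute floor on baseline band-integrated spectral
    power above the Nyquist floor; ``None`` disables the low-activity
    criterion.  Use :func:`cohort_activity_threshold` to derive it as a
    fraction (default 5%) of the cohort median.
    activity_band: frequency band (Hz) integrated for the activity test.
    """

    brightness_jump_ratio: float = 1.5
    min_band_power: float | None = None
    activity_band: tuple = (0.01, 1.0)


def activity_band_power(well: WellRecord, grid: TimeFrequencyGrid,
                        band: tuple = (0.01, 1.0)) -> float:
    """Baseline band-integrated spectral power above the Nyquist floor."""
    series = FluctuationSpectrumSeries.from_well(well, grid)
    base = baseline_average(series)
    floor = base[-1]
    sel = (grid.frequencies >= band[0]) & (grid.frequencies < band[1])
    excess = np.maximum(base[sel] - floor, 0.0)
    return float(np.trapezoid(excess, grid.frequencies[sel]))


def cohort_activity_threshold(wells, grid: TimeFrequencyGrid,
                              fraction: float = 0.05,
                              band: tuple = (0.01, 1.0)) -> float:
    """Low-activity threshold: ``fraction`` of the cohort median band power."""
    powers = [activity_band_power(w, grid, band) for w in wells]
    return fraction * float(np.median(powers))


def assess_data_quality(
    well: WellRecord,
    grid: TimeFrequencyGrid,
    thresholds: DQThresholds = DQThresholds(),
) -> float:
    """Data quality DQ = 2**(-m), halved for each violated criterion.

    Criteria counted: (a) brightness jump between consecutive loops,
    (b) low baseline cell activity (if a threshold is configured), and
    (c) every pre-assigned violation flag on the well.
    """
    m = len(well.violations)
    ratios = well.brightness[1:] / well.brightness[:-1]
    if np.any((ratios > thresholds.brightness_jump_ratio)
              | (ratios < 1.0 / thresholds.brightness_jump_ratio)):
        m += 1
    if thresholds.min_band_power is not None:
        if activity_band_power(well, grid, thresholds.activity_band) < thresholds.min_band_power:
            m += 1
    return 2.0 ** (-m)


# ---------------------------------------------------------------------------
# replicate combination


def weighted_average_spectrograms(spectrograms, dqs=None) -> DrugResponseSpectrogram:
    """DQ-weighted element-wise mean of replicate spectrograms.

    The result's DQ is the arithmetic mean of the input DQs (it no longer
    has the 2**(-m) form of a single well).
    """
    spectrograms = list(spectrograms)
    if not spectrograms:
        raise ValueError("no spectrograms to average")
    if dqs is None:
        dqs = [s.dq for s in spectrograms]
    dqs = np.asarray(dqs, dtype=float)
    if dqs.shape != (len(spectrograms),):
        raise ValueError("one DQ per spectrogram required")
    if np.all(dqs <= 0):
        raise ValueError("no usable replicates: all DQ are zero")
    grid = spectrograms[0].grid
    treatment = spectrograms[0].treatment
    for s in spectrograms[1:]:
        if s.grid != grid:
            raise ValueError("replicates must share the grid")
        if s.treatment != treatment:
            raise ValueError("replicates must share the treatment")
    stack = np.stack([s.D for s in spectrograms])
    weights = dqs / dqs.sum()
    D = np.tensordot(weights, stack, axes=1)
    return DrugResponseSpectrogram(grid=grid, D=D, treatment=treatment,
                                   dq=float(dqs.mean()))


def subtract_control(
    treatment_spgm: DrugResponseSpectrogram,
    control_spgm: DrugResponseSpectrogram | None,
    missing: str = "error",
) -> DrugResponseSpectrogram:
    """Subtract the vehicle-control spectrogram element-wise.

    With ``missing='pass'`` a missing control is tolerated and the
    treatment spectrogram is returned unchanged.
    """
    if control_spgm is None:
        if missing == "pass":
            import warnings

            warnings.warn("no control spectrogram; returning treatment unchanged")
            return treatment_spgm
        raise ValueError("control spectrogram missing")
    if control_spgm.grid != treatment_spgm.grid:
        raise ValueError("control grid does not match")
    return DrugResponseSpectrogram(
        grid=treatment_spgm.grid,
        D=treatment_spgm.D - control_spgm.D,
        treatment=treatment_spgm.treatment,
        dq=treatment_spgm.dq,
        baseline=treatment_spgm.baseline,
    )
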