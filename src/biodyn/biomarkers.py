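"""Time-frequency biomarker extraction.

Each patient x treatment spectrogram is reduced to 18 spectrogram features
(9 global + 9 local) by inner products with fixed filter masks, and 9
additional features are the drug-induced changes in the spectral
*preconditions* (NSD, BSB, NCNT, DR, NY, KNEE, HW, S, SF).  The 27
features per drug are concatenated over the three treatment arms into an
81-element patient feature vector.

Global masks are tensor products of low-order (0-2) orthogonal polynomials
along the post-dose loop axis and the log-frequency axis.  The polynomials
are built by QR orthonormalization of the degree-graded monomial basis on
the *sampled* grid points (discrete Legendre polynomials), so the nine
masks are exactly orthonormal under the grid inner product.  Local masks
are frequency-band indicators (rheology 10-100 mHz, mid 0.1-1 Hz, high
1-10 Hz) times the same order 0-2 time polynomials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .grid import TimeFrequencyGrid
from .spectrogram import DrugResponseSpectrogram

__all__ = [
    "FilterMask",
    "PreconditionSet",
    "PatientFeatureVector",
    "DEFAULT_BAND_EDGES",
    "BAND_NAMES",
    "PRECONDITION_NAMES",
    "LOG_RATIO_PRECONDITIONS",
    "build_global_masks",
    "build_local_masks",
    "spectrogram_masks",
    "project",
    "fit_preconditions",
    "precondition_deltas",
    "assemble_feature_vector",
    "feature_names",
    "spectrogram_feature_names",
]

DEFAULT_BAND_EDGES = (0.01, 0.1, 1.0, 10.0)
BAND_NAMES = ("low", "mid", "high")

#: canonical ordering of the precondition biomarkers
PRECONDITION_NAMES = ("NSD", "BSB", "NCNT", "DR", "NY", "KNEE", "HW", "S", "SF")
#: positive scale parameters whose drug-induced change is a log10 ratio
LOG_RATIO_PRECONDITIONS = ("BSB", "NY", "KNEE", "HW")
#: preconditions whose fits can fail ("unstable"): deltas imputable to 0
UNSTABLE_PRECONDITIONS = ("NCNT", "KNEE", "S")

TREATMENT_CODES = {"carboplatin": "carb", "paclitaxel": "tax", "combination": "combo"}


@dataclass(frozen=True)
class FilterMask:
    name: str
    family: str  # "global" | "local"
    weights: np.ndarray  # [n_post_loops, n_frequencies], unit Frobenius norm
    time_order: int
    freq_order: int | None = None  # global masks
    band: str | None = None  # local masks


def _orthonormal_polynomials(x: np.ndarray, max_order: int) -> np.ndarray:
    """Columns 0..max_order: discrete orthonormal polynomials on points x.

    QR of the degree-graded Vandermonde; column k is a degree-k polynomial,
    the set is exactly orthonormal under the Euclidean inner product on the
    sample points.  Signs fixed so each column correlates positively with
    its monomial.
    """
    if x.size <= max_order:
        raise ValueError("need more grid points than the polynomial order")
    V = np.vander(x, max_order + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    return Q * signs


def _axis_coordinates(grid: TimeFrequencyGrid) -> tuple:
    """Post-dose loop index and log10 frequency, affinely mapped to [-1, 1]."""
    t = grid.post_loop_indices.astype(float)
    xt = 2.0 * (t - t[0]) / (t[-1] - t[0]) - 1.0
    lf = np.log10(grid.frequencies)
    xf = 2.0 * (lf - lf[0]) / (lf[-1] - lf[0]) - 1.0
    return xt, xf


def build_global_masks(grid: TimeFrequencyGrid) -> list:
    """The 9 global masks: orders 0-2 along time and log-frequency."""
    if grid.n_post_loops < 3 or grid.n_frequencies < 3:
        raise ValueError("global masks need >= 3 post-dose loops and >= 3 frequencies")
    xt, xf = _axis_coordinates(grid)
    Pt = _orthonormal_polynomials(xt, 2)
    Pf = _orthonormal_polynomials(xf, 2)
    masks = []
    for i in range(3):
        for j in range(3):
            weights = np.outer(Pt[:, i], Pf[:, j])
            masks.append(FilterMask(name=f"glob.t{i}f{j}", family="global",
                                    weights=weights, time_order=i, freq_order=j))
    return masks


def build_local_masks(grid: TimeFrequencyGrid,
                      band_edges: tuple = DEFAULT_BAND_EDGES) -> list:
    """The 9 local masks: band indicators x order 0-2 time polynomials.

    Bands are half-open ``[lo, hi)`` so adjacent bands share no grid
    frequency; the sub-band below the first edge and the Nyquist region
    above the last edge carry zero weight.
    """
    edges = np.asarray(band_edges, dtype=float)
    if edges.size != len(BAND_NAMES) + 1 or np.any(np.diff(edges) <= 0):
        raise ValueError("band_edges must be 4 strictly increasing frequencies")
    if edges[0] < grid.frequencies[0] - 1e-12 or edges[-1] > grid.frequencies[-1] + 1e-12:
        raise ValueError("band edges must lie within the frequency grid")
    if grid.n_post_loops < 3:
        raise ValueError("local masks need >= 3 post-dose loops")
    xt, _ = _axis_coordinates(grid)
    Pt = _orthonormal_polynomials(xt, 2)
    masks = []
    for b, band in enumerate(BAND_NAMES):
        sel = (grid.frequencies >= edges[b]) & (grid.frequencies < edges[b + 1])
        if not np.any(sel):
            raise ValueError(f"band {band!r} contains no grid frequencies")
        indicator = sel.astype(float)
        indicator /= np.linalg.norm(indicator)
        for k in range(3):
            weights = np.outer(Pt[:, k], indicator)
            masks.append(FilterMask(name=f"loc.{band}.t{k}", family="local",
                                    weights=weights, time_order=k, band=band))
    return masks


def spectrogram_masks(grid: TimeFrequencyGrid,
                      band_edges: tuple = DEFAULT_BAND_EDGES) -> list:
    """All 18 masks in canonical order: 9 global then 9 local."""
    return build_global_masks(grid) + build_local_masks(grid, band_edges)


def project(spectrogram, masks) -> np.ndarray:
    """Grid inner products of the spectrogram with each mask."""
    D = spectrogram.D if isinstance(spectrogram, DrugResponseSpectrogram) else np.asarray(spectrogram)
    out = np.empty(len(masks))
    for k, mask in enumerate(masks):
        if mask.weights.shape != D.shape:
            raise ValueError(f"mask {mask.name!r} shape does not match spectrogram")
        out[k] = float(np.sum(mask.weights * D))
    return out


# ---------------------------------------------------------------------------
# preconditions


@dataclass
class PreconditionSet:
    """Pre- or post-dose spectral/sample preconditions of one specimen.

    Unstable quantities (KNEE, S and the derived HW) carry convergence
    flags; a failed fit stores NaN.
    """

    nsd: float  # speckle contrast
    bsb: float  # brightness
    ncnt: float  # sample size (count)
    dr: float  # dynamic range, log10 units
    ny: float  # Nyquist-floor spectral density
    knee: float  # knee frequency, Hz
    hw: float  # spectral half-width, Hz
    s: float  # roll-off slope
    sf: float  # high-frequency secondary slope
    knee_converged: bool = True
    s_converged: bool = True

    def as_dict(self) -> dict:
        return {"NSD": self.nsd, "BSB": self.bsb, "NCNT": self.ncnt,
                "DR": self.dr, "NY": self.ny, "KNEE": self.knee,
                "HW": self.hw, "S": self.s, "SF": self.sf}


def _half_width(freqs: np.ndarray, spectrum: np.ndarray, ny: float,
                amplitude: float) -> float:
    """Frequency where the floor-subtracted spectrum first falls to A/2,
    by log-log interpolation of the measured curve."""
    excess = spectrum - ny
    target = amplitude / 2.0
    below = np.nonzero(excess <= target)[0]
    if below.size == 0 or below[0] == 0:
        return math.nan
    i = below[0]
    x0, x1 = np.log(freqs[i - 1]), np.log(freqs[i])
    y0, y1 = excess[i - 1], excess[i]
    if y0 == y1:
        return float(freqs[i])
    return float(np.exp(x0 + (x1 - x0) * (y0 - target) / (y0 - y1)))


def fit_preconditions(
    baseline_spectrum: np.ndarray,
    grid: TimeFrequencyGrid,
    nsd: float = math.nan,
    bsb: float = math.nan,
    ncnt: float = math.nan,
) -> PreconditionSet:
    """Fit the plateau-knee-roll-off model to a baseline spectrum.

    NY is the spectral density read from the top (Nyquist) frequency bin;
    A, KNEE and S are fit by least squares on the log10 densities.  The
    knee's power-law tail still contributes at Nyquist, so the fit refines
    the additive floor as a nuisance parameter initialized at NY (the
    reported NY stays the measured top-bin density).  HW is the measured
    half-power frequency; DR = log10((A + floor)/floor) with the fitted
    floor; SF is the local log-log slope over the top half-decade below
    Nyquist.  NSD, BSB and NCNT are pass-through sample metadata.
    """
    spec = np.asarray(baseline_spectrum, dtype=float)
    freqs = grid.frequencies
    if spec.shape != freqs.shape:
        raise ValueError("spectrum length must match the grid")
    if np.any(spec <= 0):
        raise ValueError("baseline spectrum must be strictly positive")

    ny = float(spec[-1])
    log_data = np.log10(spec)

    def residuals(theta):
        log_a, log_knee, s, log_floor = theta
        model = (10.0 ** log_a / (1.0 + (freqs / 10.0 ** log_knee) ** s)
                 + 10.0 ** log_floor)
        return np.log10(model) - log_data

    a0 = max(spec[0] - ny, ny * 1e-3)
    half = _half_width(freqs, spec, ny, a0)
    knee0 = half if math.isfinite(half) else math.sqrt(freqs[0] * freqs[-1])
    theta0 = np.array([math.log10(a0), math.log10(knee0), 1.5,
                       math.log10(ny)])
    lo = [math.log10(ny * 1e-6), math.log10(freqs[0]), 0.05,
          math.log10(ny * 1e-3)]
    hi = [math.log10(spec.max() * 10), math.log10(freqs[-1]), 10.0,
          math.log10(ny * 1.001)]
    theta0 = np.clip(theta0, lo, hi)
    try:
        fit = least_squares(residuals, theta0, bounds=(lo, hi))
        converged = bool(fit.success)
        log_a, log_knee, s, log_floor = fit.x
        amplitude = 10.0 ** log_a
        knee = 10.0 ** log_knee
        floor = 10.0 ** log_floor
        # a knee pinned to the grid edge is not a trustworthy fit
        if knee <= freqs[0] * 1.01 or knee >= freqs[-1] * 0.99:
            converged = False
    except Exception:
        converged = False
        amplitude, knee, s, floor = a0, math.nan, math.nan, ny

    if not converged:
        knee = math.nan
        s = math.nan

    hw = _half_width(freqs, spec, floor, amplitude)
    dr = math.log10((amplitude + floor) / floor)

    top = freqs >= freqs[-1] / 10 ** 0.5
    slope = np.polyfit(np.log10(freqs[top]), log_data[top], 1)[0]

    return PreconditionSet(
        nsd=float(nsd), bsb=float(bsb), ncnt=float(ncnt), dr=float(dr),
        ny=ny, knee=float(knee), hw=float(hw), s=float(s), sf=float(slope),
        knee_converged=converged, s_converged=converged,
    )


def precondition_deltas(pre: PreconditionSet, post: PreconditionSet) -> tuple:
    """Drug-induced precondition changes, baseline -> assay endpoint.

    Positive scale parameters (BSB, NY, KNEE, HW) change as log10 ratios
    post/pre; the remainder as arithmetic differences.  A delta involving a
    failed fit (NaN) is imputed to 0 (no change) and reported in the
    returned flag list.

    Returns (deltas[9] in canonical order, imputed_names).
    """
    pre_d, post_d = pre.as_dict(), post.as_dict()
    deltas = np.empty(len(PRECONDITION_NAMES))
    imputed = []
    for i, name in enumerate(PRECONDITION_NAMES):
        a, b = pre_d[name], post_d[name]
        if name in LOG_RATIO_PRECONDITIONS:
            value = math.log10(b / a) if (a > 0 and b > 0 and math.isfinite(a) and math.isfinite(b)) else math.nan
        else:
            value = b - a
        if not math.isfinite(value):
            imputed.append(name)
            value = 0.0
        deltas[i] = value
    return deltas, imputed


# ---------------------------------------------------------------------------
# feature vector assembly


@dataclass
class PatientFeatureVector:
    """81 features: [carboplatin | paclitaxel | combination] blocks of
    18 spectrogram features + 9 precondition deltas each."""

    patient_id: str
    values: np.ndarray
    label: int  # -1 resistant, +1 sensitive
    cohort_tag: str = "training"
    imputed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_features(self) -> int:
        return int(self.values.size)


def spectrogram_feature_names(band_edges: tuple = DEFAULT_BAND_EDGES) -> list:
    names = [f"glob.t{i}f{j}" for i in range(3) for j in range(3)]
    names += [f"loc.{band}.t{k}" for band in BAND_NAMES for k in range(3)]
    return names


def feature_names(drop_unstable: bool = False) -> list:
    """Column names of the assembled feature vector, in storage order."""
    precond = [n for n in PRECONDITION_NAMES
               if not (drop_unstable and n in UNSTABLE_PRECONDITIONS)]
    names = []
    for treatment in ("carboplatin", "paclitaxel", "combination"):
        code = TREATMENT_CODES[treatment]
        names += [f"{code}.{n}" for n in spectrogram_feature_names()]
        names += [f"{code}.pre.d{n}" for n in precond]
    return names


def assemble_feature_vector(
    blocks: dict,
    patient_id: str,
    label: int,
    cohort_tag: str = "training",
    imputed: dict | None = None,
    drop_unstable: bool = False,
) -> PatientFeatureVector:
    """Concatenate the per-drug 27-feature blocks into the 81-vector.

    ``blocks`` must be keyed explicitly by the three drug treatments;
    block order in the output is fixed (carboplatin, paclitaxel,
    combination) regardless of dict ordering.  With ``drop_unstable`` the
    NCNT/KNEE/S deltas are removed and each block shrinks to 24.
    """
    expected = set(TREATMENT_CODES)
    if set(blocks) != expected:
        missing = expected - set(blocks)
        extra = set(blocks) - expected
        raise ValueError(
            f"feature blocks must be keyed by {sorted(expected)}; "
            f"missing {sorted(missing)}, unexpected {sorted(extra)}"
        )
    block_len = 24 if drop_unstable else 27
    parts = []
    for treatment in ("carboplatin", "paclitaxel", "combination"):
        block = np.asarray(blocks[treatment], dtype=float)
        if block.size != block_len:
            raise ValueError(
                f"{treatment} block has {block.size} features, expected {block_len}"
            )
        parts.append(block)
    return PatientFeatureVector(
        patient_id=patient_id,
        values=np.concatenate(parts),
        label=int(label),
        cohort_tag=cohort_tag,
        imputed=imputed or {},
    )
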