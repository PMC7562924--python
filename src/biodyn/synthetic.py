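"""Synthetic cohort generator for biodynamic chemosensitivity assays.

Emulates the statistical structure the downstream analysis assumes: each
well carries a Doppler fluctuation spectrum with a low-frequency plateau,
a knee, a power-law roll-off and a Nyquist noise floor,

    S(omega) = A / (1 + (omega / omega_k)**s) + NY,

sampled once per loop.  Drug action enters as a slow post-dose ramp of two
multiplicative factors: a knee factor kappa(t) that shifts the Doppler knee
(kappa < 1 slows average intracellular motion, the spectral "red shift")
and an amplitude factor alpha(t) that scales the dynamic part of the
spectrum (alpha < 1 is broadband inhibition).  Resistant tissue responds to
the platinum/taxane monotherapies with a red shift (kappa < 1, alpha ~
1/kappa so spectral power migrates rather than vanishes); sensitive tissue
shows a mild blue shift; the combination inhibits both phenotypes
broadband; vehicle control leaves both factors at unity.  Metastatic
specimens always carry resistant-type response parameters, whatever their
clinical label.

Patient-to-patient biological heterogeneity is modelled as a log-normal
jitter of the per-treatment endpoint factors; per-bin measurement noise is
multiplicative log-normal so it becomes additive Gaussian on the log
spectrogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import TimeFrequencyGrid

__all__ = [
    "TREATMENTS",
    "DRUG_TREATMENTS",
    "CONTROL",
    "PHENOTYPES",
    "LABEL_OF_PHENOTYPE",
    "ResponseEndpoint",
    "PhenotypeParams",
    "AssayDesign",
    "WellRecord",
    "PatientRecord",
    "Cohort",
    "baseline_doppler_spectrum",
    "drug_response_modifier",
    "simulate_well",
    "simulate_cohort",
]

CONTROL = "control"
DRUG_TREATMENTS = ("carboplatin", "paclitaxel", "combination")
TREATMENTS = (CONTROL,) + DRUG_TREATMENTS
PHENOTYPES = ("resistant", "sensitive")

#: sign convention: resistant phenotype maps to negative chemosensitivity
LABEL_OF_PHENOTYPE = {"resistant": -1, "sensitive": +1}

#: violation criteria the generator can inject.  "brightness_jump" is
#: injected physically (a step in the brightness trajectory that the data
#: quality assessment detects); the others are carried as pre-assigned flags.
INJECTABLE_FLAGS = ("debris", "stage_drift", "meniscus")


@dataclass(frozen=True)
class ResponseEndpoint:
    """Endpoint (final-loop) values of the two drug-response factors.

    Both factors ramp linearly in time from 1 at the dose to these values
    at the last loop of the assay.
    """

    knee_factor: float = 1.0
    amplitude_factor: float = 1.0


def _default_responses() -> dict:
    red_shift = ResponseEndpoint(knee_factor=0.5, amplitude_factor=2.0)
    mild_blue = ResponseEndpoint(knee_factor=1.1, amplitude_factor=1.0 / 1.1)
    inhibition = ResponseEndpoint(knee_factor=1.0, amplitude_factor=0.5)
    return {
        ("resistant", "carboplatin"): red_shift,
        ("resistant", "paclitaxel"): red_shift,
        ("resistant", "combination"): inhibition,
        ("sensitive", "carboplatin"): mild_blue,
        ("sensitive", "paclitaxel"): mild_blue,
        ("sensitive", "combination"): inhibition,
        ("resistant", CONTROL): ResponseEndpoint(),
        ("sensitive", CONTROL): ResponseEndpoint(),
    }


@dataclass(frozen=True)
class PhenotypeParams:
    """Spectral-shape and response parameters of the generator.

    amplitude, knee_hz, rolloff, nyquist_floor parameterize the baseline
    Doppler spectrum; responses maps (phenotype, treatment) to endpoint
    factors; sigma_log is the per-bin multiplicative noise in log10 units;
    patient_sigma is the sd (natural log) of the per-(patient, treatment)
    jitter applied to the endpoint factors; violation_prob is the
    per-criterion injection probability (four independent criteria at the
    default 0.59 give a typical data quality near 0.25).
    """

    amplitude: float = 100.0
    knee_hz: float = 0.3
    rolloff: float = 1.6
    nyquist_floor: float = 1.0
    sigma_log: float = 0.05
    patient_sigma: float = 0.25
    violation_prob: float = 0.59
    responses: dict = field(default_factory=_default_responses)
    # well metadata emitted for the precondition biomarkers
    brightness_mean: float = 2000.0
    speckle_contrast: float = 0.45
    sample_count: int = 1200

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.nyquist_floor <= 0:
            raise ValueError("amplitude and nyquist_floor must be positive")
        if self.knee_hz <= 0 or self.rolloff <= 0:
            raise ValueError("knee_hz and rolloff must be positive")
        if self.sigma_log < 0 or self.patient_sigma < 0:
            raise ValueError("noise scales must be non-negative")
        if not 0 <= self.violation_prob <= 1:
            raise ValueError("violation_prob must be a probability")
        for phenotype in PHENOTYPES:
            ctrl = self.responses.get((phenotype, CONTROL), ResponseEndpoint())
            if ctrl.knee_factor != 1.0 or ctrl.amplitude_factor != 1.0:
                raise ValueError("control trajectories must be identically (1, 1)")


@dataclass(frozen=True)
class AssayDesign:
    """Cohort layout: patient counts per class and replicate wells per arm."""

    n_resistant: int = 10
    n_sensitive: int = 10
    n_metastatic: int = 4
    wells_per_treatment: dict = field(
        default_factory=lambda: {
            CONTROL: 17,
            "paclitaxel": 18,
            "carboplatin": 18,
            "combination": 18,
        }
    )
    immobilization: str = "poly-lysine"
    metastatic_clinical_label: str = "sensitive"

    def __post_init__(self) -> None:
        if self.n_resistant < 1 or self.n_sensitive < 1:
            raise ValueError(
                "designs need at least one resistant and one sensitive patient "
                "for downstream training"
            )
        if self.n_metastatic < 0:
            raise ValueError("n_metastatic must be non-negative")
        for treatment, n in self.wells_per_treatment.items():
            if treatment not in TREATMENTS:
                raise ValueError(f"unknown treatment {treatment!r}")
            if n < 1:
                raise ValueError("well counts must be >= 1")

    @property
    def wells_per_patient(self) -> int:
        return sum(self.wells_per_treatment.values())


@dataclass
class WellRecord:
    """One well: spectra on the shared grid plus acquisition metadata."""

    well_id: str
    patient_id: str
    treatment: str
    spectra: np.ndarray  # [n_loops, n_frequencies], strictly positive
    brightness: np.ndarray  # per loop
    violations: list = field(default_factory=list)
    immobilization: str = "poly-lysine"
    speckle_contrast: float = 0.45
    sample_count: int = 1200

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.brightness = np.asarray(self.brightness, dtype=float)
        if np.any(self.spectra <= 0) or not np.all(np.isfinite(self.spectra)):
            raise ValueError("well spectra must be strictly positive and finite")
        if self.spectra.shape[0] != self.brightness.shape[0]:
            raise ValueError("brightness must have one value per loop")


@dataclass
class PatientRecord:
    patient_id: str
    clinical_label: str  # "resistant" | "sensitive"
    cohort_tag: str  # "training" | "metastatic" | "test"
    response_phenotype: str  # phenotype driving the simulated drug response
    wells: list = field(default_factory=list)

    @property
    def y(self) -> int:
        return LABEL_OF_PHENOTYPE[self.clinical_label]


@dataclass
class Cohort:
    grid: TimeFrequencyGrid
    patients: list
    seed: int | None = None

    def patient(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)


# ---------------------------------------------------------------------------
# spectral model


def baseline_doppler_spectrum(
    params: PhenotypeParams, grid: TimeFrequencyGrid
) -> np.ndarray:
    """Noise-free baseline spectrum S(omega) = A/(1+(omega/omega_k)**s) + NY."""
    omega = grid.frequencies
    return params.amplitude / (1.0 + (omega / params.knee_hz) ** params.rolloff) + (
        params.nyquist_floor
    )


def drug_response_modifier(
    phenotype: str,
    treatment: str,
    loop: int,
    params: PhenotypeParams,
    grid: TimeFrequencyGrid,
    endpoint: ResponseEndpoint | None = None,
) -> tuple:
    """(knee factor, amplitude factor) at a given loop.

    Both factors are 1 for every pre-dose loop and for the vehicle control,
    and ramp linearly from 1 just before the dose to the endpoint values at
    the final loop.  ``endpoint`` overrides the configured endpoint (used to
    apply per-patient jitter); by default the (phenotype, treatment) entry
    of ``params.responses`` is used.
    """
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}")
    if treatment == CONTROL:
        return (1.0, 1.0)
    if endpoint is None:
        endpoint = params.responses[(phenotype, treatment)]
    last_pre = grid.dose_loop - 1
    last_loop = grid.n_loops - 1
    if loop <= last_pre:
        return (1.0, 1.0)
    u = (loop - last_pre) / (last_loop - last_pre)
    knee = 1.0 + (endpoint.knee_factor - 1.0) * u
    amp = 1.0 + (endpoint.amplitude_factor - 1.0) * u
    return (knee, amp)


def _modified_spectrum(
    params: PhenotypeParams, grid: TimeFrequencyGrid, knee_factor: float, amp_factor: float
) -> np.ndarray:
    omega = grid.frequencies
    knee = params.knee_hz * knee_factor
    dynamic = params.amplitude * amp_factor / (1.0 + (omega / knee) ** params.rolloff)
    return dynamic + params.nyquist_floor


# ---------------------------------------------------------------------------
# well and cohort simulation


def simulate_well(
    params: PhenotypeParams,
    grid: TimeFrequencyGrid,
    phenotype: str,
    treatment: str,
    rng: np.random.Generator,
    well_id: str = "w00",
    patient_id: str = "p00",
    endpoint: ResponseEndpoint | None = None,
    inject_violations: bool = True,
    immobilization: str = "poly-lysine",
) -> WellRecord:
    """Simulate one well on the shared grid.

    Spectra are the ramped model spectrum times multiplicative log-normal
    noise ``10**(sigma_log * eps)`` with eps i.i.d. standard normal per
    (frequency, loop) bin; sigma_log = 0 reproduces the noiseless model
    exactly.  With ``inject_violations`` each quality criterion is violated
    independently with probability ``params.violation_prob``: a brightness
    jump is injected as a x2 step in the brightness trajectory (detected
    downstream), the remaining criteria as pre-assigned flags.
    """
    n_loops = grid.n_loops
    spectra = np.empty((n_loops, grid.n_frequencies))
    for t in range(n_loops):
        kf, af = drug_response_modifier(phenotype, treatment, t, params, grid, endpoint)
        spectra[t] = _modified_spectrum(params, grid, kf, af)
    if params.sigma_log > 0:
        eps = rng.standard_normal(spectra.shape)
        spectra = spectra * 10.0 ** (params.sigma_log * eps)

    brightness = params.brightness_mean * (1.0 + 0.02 * rng.standard_normal(n_loops))
    violations: list = []
    if inject_violations:
        if rng.random() < params.violation_prob:
            # immobilization shift: step change detected by the DQ assessment
            jump_loop = int(rng.integers(1, n_loops))
            brightness[jump_loop:] *= 2.0
        for flag in INJECTABLE_FLAGS:
            if rng.random() < params.violation_prob:
                violations.append(flag)

    return WellRecord(
        well_id=well_id,
        patient_id=patient_id,
        treatment=treatment,
        spectra=spectra,
        brightness=brightness,
        violations=violations,
        immobilization=immobilization,
        speckle_contrast=params.speckle_contrast
        * (1.0 + 0.02 * rng.standard_normal()),
        sample_count=int(params.sample_count + rng.integers(-100, 101)),
    )


def _jittered_endpoint(
    base: ResponseEndpoint, sigma: float, rng: np.random.Generator
) -> ResponseEndpoint:
    """Log-normal per-(patient, treatment) jitter of the endpoint factors."""
    if sigma == 0:
        return base
    kf = base.knee_factor * np.exp(sigma * rng.standard_normal())
    af = base.amplitude_factor * np.exp(sigma * rng.standard_normal())
    return ResponseEndpoint(knee_factor=kf, amplitude_factor=af)


def simulate_cohort(
    design: AssayDesign,
    params: PhenotypeParams,
    grid: TimeFrequencyGrid,
    seed: int,
) -> Cohort:
    """Simulate a full cohort.

    Training patients split into resistant/sensitive clinical classes;
    metastatic patients carry the configured clinical label (sensitive by
    default, mirroring metastatic implants from clinically sensitive
    patients) but always respond with resistant-type parameters.
    """
    rng = np.random.default_rng(seed)
    patients: list = []

    roster = (
        [("resistant", "training")] * design.n_resistant
        + [("sensitive", "training")] * design.n_sensitive
        + [(design.metastatic_clinical_label, "metastatic")] * design.n_metastatic
    )
    for idx, (clinical, tag) in enumerate(roster):
        pid = f"pt{idx:02d}" + ("m" if tag == "metastatic" else "")
        response_phenotype = "resistant" if tag == "metastatic" else clinical
        patient = PatientRecord(
            patient_id=pid,
            clinical_label=clinical,
            cohort_tag=tag,
            response_phenotype=response_phenotype,
        )
        endpoints = {
            treatment: _jittered_endpoint(
                params.responses[(response_phenotype, treatment)],
                params.patient_sigma,
                rng,
            )
            for treatment in DRUG_TREATMENTS
        }
        well_no = 0
        for treatment in TREATMENTS:
            n_wells = design.wells_per_treatment.get(treatment, 0)
            for _ in range(n_wells):
                well = simulate_well(
                    params,
                    grid,
                    response_phenotype,
                    treatment,
                    rng,
                    well_id=f"{pid}-w{well_no:02d}",
                    patient_id=pid,
                    endpoint=endpoints.get(treatment),
                    immobilization=design.immobilization,
                )
                patient.wells.append(well)
                well_no += 1
        patients.append(patient)

    return Cohort(grid=grid, patients=patients, seed=seed)
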