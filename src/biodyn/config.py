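"""Pipeline configuration and seeded random substreams.

Every stage of the pipeline reads its parameters from one
:class:`PipelineConfig`.  Defaults follow the assay protocol wherever the
protocol fixes a value (k = 3 network neighbors, ridge lambda = 0.1,
25 fps camera -> 12.5 Hz Nyquist, 82-min loops, 4 baseline + 9 post-dose
loops, 17/18/18/18 replicate wells); everything else is a documented
package default.  All randomness flows from one master seed through named
per-stage substreams.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .grid import TimeFrequencyGrid
from .synthetic import AssayDesign, PhenotypeParams

__all__ = ["PipelineConfig", "load_config", "stage_rng"]

_STAGES = ("simulate", "classify", "evaluate")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named deterministic substream of the master seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGES.index(stage),))
    return np.random.default_rng(ss)


@dataclass
class PipelineConfig:
    # grid
    n_frequencies: int = 50
    f_min: float = 0.01
    f_max: float = 12.5
    n_pre_loops: int = 4
    n_post_loops: int = 9
    loop_period_min: float = 82.0
    frame_rate: float = 25.0
    # spectrogram / biomarkers
    band_edges: tuple = (0.01, 0.1, 1.0, 10.0)
    log_base: float = 10.0
    dmso_subtract: bool = True
    brightness_jump_ratio: float = 1.5
    low_activity_fraction: float = 0.05
    drop_unstable_preconditions: bool = False
    # selection / classification
    n_select: int = 5
    k: int = 3
    lam: float = 0.1
    n_resamples: int = 8
    resample_frac: float = 0.8
    sigma_floor: float = 0.02
    # cohort design
    n_resistant: int = 10
    n_sensitive: int = 10
    n_metastatic: int = 4
    wells_per_treatment: dict = field(default_factory=lambda: {
        "control": 17, "paclitaxel": 18, "carboplatin": 18, "combination": 18})
    # generator
    amplitude: float = 100.0
    knee_hz: float = 0.3
    rolloff: float = 1.6
    nyquist_floor: float = 1.0
    sigma_log: float = 0.05
    patient_sigma: float = 0.25
    violation_prob: float = 0.59
    # bookkeeping
    seed: int = 1
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("config key 'k' must be >= 1")
        if self.lam < 0:
            raise ValueError("config key 'lam' must be non-negative")
        if self.n_select < 1:
            raise ValueError("config key 'n_select' must be >= 1")
        if self.frame_rate <= 0:
            raise ValueError("config key 'frame_rate' must be positive")
        if self.n_pre_loops < 4:
            raise ValueError("config key 'n_pre_loops' must be >= 4 "
                             "(baseline uses the last 4 pre-dose loops)")
        if self.n_post_loops < 3:
            raise ValueError("config key 'n_post_loops' must be >= 3")
        if self.log_base != 10.0:
            raise ValueError("config key 'log_base': only base 10 is supported")
        if not 0 < self.sigma_floor:
            raise ValueError("config key 'sigma_floor' must be positive")
        if self.f_max != self.frame_rate / 2.0:
            raise ValueError("config key 'f_max' must equal the Nyquist "
                             "frequency frame_rate/2")
        self.band_edges = tuple(float(v) for v in self.band_edges)

    # -- derived objects ----------------------------------------------------

    def grid(self) -> TimeFrequencyGrid:
        return TimeFrequencyGrid.default(
            n_frequencies=self.n_frequencies, f_min=self.f_min, f_max=self.f_max,
            n_pre_loops=self.n_pre_loops, n_post_loops=self.n_post_loops,
            loop_period_min=self.loop_period_min,
        )

    def design(self) -> AssayDesign:
        return AssayDesign(
            n_resistant=self.n_resistant, n_sensitive=self.n_sensitive,
            n_metastatic=self.n_metastatic,
            wells_per_treatment=dict(self.wells_per_treatment),
        )

    def phenotype_params(self) -> PhenotypeParams:
        return PhenotypeParams(
            amplitude=self.amplitude, knee_hz=self.knee_hz, rolloff=self.rolloff,
            nyquist_floor=self.nyquist_floor, sigma_log=self.sigma_log,
            patient_sigma=self.patient_sigma, violation_prob=self.violation_prob,
        )


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML ``key: value`` configuration.

    Unknown keys are rejected by name; missing keys take their defaults;
    an empty (or absent) file yields the default configuration.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must be a mapping of key: value")
        data.update(loaded)
    if overrides:
        data.update(overrides)
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
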