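"""Cross-validated outcome evaluation.

Training patients are predicted by leave-one-out cross-validation with the
biomarker selection and standardization refit inside every fold; metastatic
and test patients are predicted by the model trained on the full training
cohort and never enter any fold.  Per-class prediction distributions are
modelled as equal-weight Gaussian mixtures over the patients' (mean, SE)
pairs; the ROC is obtained by sweeping a threshold through the two
continuous mixtures, which makes it insensitive to the discreteness of a
small cohort.

Scoring convention: the R-class (resistant *and* metastatic specimens)
lies at negative predicted chemosensitivity; the S-class (sensitive
non-metastatic) at positive values.  Sensitivity is the R-mixture mass
below the threshold; specificity is the S-mixture mass above it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .classifiers import TrainingSet, ensemble_predict
from .feature_space import select_biomarkers

__all__ = [
    "PatientPrediction",
    "MixturePDF",
    "ROCReport",
    "loocv",
    "mixture_pdf",
    "roc_from_mixture",
    "decision_metrics",
    "mean_separation",
    "evaluate_predictions",
]


@dataclass
class PatientPrediction:
    patient_id: str
    mean: float
    se: float
    label: int  # clinical label, -1 resistant / +1 sensitive
    cohort_tag: str = "training"
    per_classifier: dict = field(default_factory=dict)

    @property
    def r_class(self) -> bool:
        """R-class groups resistant and metastatic specimens."""
        return self.cohort_tag == "metastatic" or self.label == -1

    def assigned_class(self, threshold: float = 0.0) -> str:
        return "R" if self.mean < threshold else "S"


# ---------------------------------------------------------------------------
# LOOCV


def _treatment_blocks(features, patient_indices):
    """Split 81-vectors into per-treatment 18-column spectrogram blocks."""
    blocks = {}
    block_len = features.values_matrix.shape[1] // 3
    n_spec = 18
    for t_idx, treatment in enumerate(("carboplatin", "paclitaxel", "combination")):
        start = t_idx * block_len
        blocks[treatment] = features.values_matrix[
            np.ix_(patient_indices, range(start, start + n_spec))
        ]
    return blocks


@dataclass
class CohortFeatures:
    """Assembled feature vectors of a whole cohort."""

    ids: list
    values_matrix: np.ndarray  # [n_patients, 81]
    labels: np.ndarray  # +/-1
    cohort_tags: list

    def __post_init__(self) -> None:
        self.values_matrix = np.atleast_2d(np.asarray(self.values_matrix, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def training_indices(self) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.cohort_tags) if t == "training"])

    @property
    def holdout_indices(self) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.cohort_tags) if t != "training"],
                        dtype=int)


def _fit_and_predict(features: CohortFeatures, fit_idx: np.ndarray,
                     predict_idx, rng, n_select: int, k: int, lam: float,
                     n_resamples: int) -> list:
    """Select biomarkers on ``fit_idx`` patients, train the ensemble on
    them, predict each patient in ``predict_idx``."""
    train_blocks = _treatment_blocks(features, fit_idx)
    selector = select_biomarkers(train_blocks, features.labels[fit_idx],
                                 n_select=min(n_select, 18 * 3))
    all_blocks = _treatment_blocks(features, np.arange(len(features.ids)))
    selected = selector.transform(all_blocks)
    train = TrainingSet(F=selected[fit_idx], y=features.labels[fit_idx],
                        ids=[features.ids[i] for i in fit_idx])
    preds = []
    for i in predict_idx:
        ep = ensemble_predict(train, selected[i], rng,
                              patient_id=features.ids[i], k=k, lam=lam,
                              n_resamples=n_resamples)
        preds.append(PatientPrediction(
            patient_id=features.ids[i], mean=ep.mean, se=ep.se,
            label=int(features.labels[i]), cohort_tag=features.cohort_tags[i],
            per_classifier=ep.per_classifier,
        ))
    return preds


def loocv(features: CohortFeatures, rng: np.random.Generator,
          n_select: int = 5, k: int = 3, lam: float = 0.1,
          n_resamples: int = 8) -> list:
    """Leave-one-out predictions for training patients plus full-model
    predictions for metastatic/test patients.

    Each training fold refits the standardization, SVD and z-factor
    selection on the remaining training patients, so no information from
    the held-out patient (or from any metastatic/test patient) leaks into
    feature selection or training.  Folds whose remaining patients contain
    a single class are skipped with a warning.
    """
    train_idx = features.training_indices
    if train_idx.size < 3:
        raise ValueError("LOOCV needs at least 3 training patients")
    if np.unique(features.labels[train_idx]).size < 2:
        raise ValueError("training cohort must contain both classes")

    preds: list = []
    for i in train_idx:
        fold = np.array([j for j in train_idx if j != i])
        counts = [np.sum(features.labels[fold] == c) for c in (-1, 1)]
        if min(counts) < 2:
            # z-factor selection and the per-class Gaussians both need >= 2
            # members per class among the remaining training patients
            import warnings

            warnings.warn(f"fold holding out {features.ids[i]} leaves a "
                          "class with < 2 members; skipped")
            continue
        preds.extend(_fit_and_predict(features, fold, [i], rng,
                                      n_select, k, lam, n_resamples))
    holdout = features.holdout_indices
    if holdout.size:
        preds.extend(_fit_and_predict(features, train_idx, holdout, rng,
                                      n_select, k, lam, n_resamples))
    return preds


# ---------------------------------------------------------------------------
# Gaussian mixture PDFs and ROC


@dataclass
class MixturePDF:
    """Equal-weight Gaussian mixture over per-patient (mean, SE) pairs."""

    means: np.ndarray
    sigmas: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.atleast_1d(np.asarray(self.means, dtype=float))
        self.sigmas = np.atleast_1d(np.asarray(self.sigmas, dtype=float))
        if self.means.size == 0:
            raise ValueError("mixture needs at least one component")
        if self.means.shape != self.sigmas.shape or np.any(self.sigmas <= 0):
            raise ValueError("each component needs a positive sigma")

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        dens = norm.pdf(x[..., None], loc=self.means, scale=self.sigmas)
        return dens.mean(axis=-1)

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        mass = norm.cdf(x[..., None], loc=self.means, scale=self.sigmas)
        return mass.mean(axis=-1)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.integers(self.means.size, size=n)
        return rng.normal(self.means[comp], self.sigmas[comp])


def mixture_pdf(predictions, sigma_floor: float = 0.02) -> MixturePDF:
    """Class mixture from a list of :class:`PatientPrediction` (or
    (mean, se) pairs); SEs are floored at ``sigma_floor`` to avoid delta
    functions when a patient's classifiers agree exactly."""
    mus, sigs = [], []
    for p in predictions:
        if isinstance(p, PatientPrediction):
            mu, se = p.mean, p.se
        else:
            mu, se = p
        mus.append(mu)
        sigs.append(max(se, sigma_floor))
    if not mus:
        raise ValueError("empty prediction class")
    return MixturePDF(means=np.array(mus), sigmas=np.array(sigs))


@dataclass
class ROCReport:
    thresholds: np.ndarray
    sensitivity: np.ndarray  # R-mixture mass below threshold
    specificity: np.ndarray  # S-mixture mass above threshold
    auc: float
    fixed: dict = field(default_factory=dict)
    optimal: dict = field(default_factory=dict)
    mean_separation: float = math.nan
    separation_ci: tuple = (math.nan, math.nan)
    per_patient: list = field(default_factory=list)


def roc_from_mixture(mix_r: MixturePDF, mix_s: MixturePDF,
                     n_thresholds: int = 4001) -> ROCReport:
    """ROC by sweeping a threshold through the two class mixtures.

    R-class (resistant/metastatic) is the positive class and lies at lower
    prediction values: sensitivity(th) = CDF_R(th), specificity(th) =
    1 - CDF_S(th).  AUC by trapezoidal integration of sensitivity against
    the false-positive rate.
    """
    lo = min(mix_r.means.min() - 6 * mix_r.sigmas.max(),
             mix_s.means.min() - 6 * mix_s.sigmas.max())
    hi = max(mix_r.means.max() + 6 * mix_r.sigmas.max(),
             mix_s.means.max() + 6 * mix_s.sigmas.max())
    thresholds = np.linspace(lo, hi, n_thresholds)
    sens = mix_r.cdf(thresholds)
    spec = 1.0 - mix_s.cdf(thresholds)
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    return ROCReport(thresholds=thresholds, sensitivity=sens,
                     specificity=spec, auc=auc)


def decision_metrics(mix_r: MixturePDF, mix_s: MixturePDF, n_r: int, n_s: int,
                     threshold: float) -> dict:
    """Clinical-style metrics at one decision threshold.

    Prevalence for accuracy/PPV/NPV comes from the cohort counts; a
    specificity of exactly 1 reports PLR as infinity.
    """
    sens = float(mix_r.cdf(np.array(threshold)))
    spec = float(1.0 - mix_s.cdf(np.array(threshold)))
    acc = (sens * n_r + spec * n_s) / (n_r + n_s)
    plr = math.inf if spec == 1.0 else sens / (1.0 - spec)
    nlr = math.inf if spec == 0.0 else (1.0 - sens) / spec
    ppv_den = sens * n_r + (1.0 - spec) * n_s
    npv_den = spec * n_s + (1.0 - sens) * n_r
    ppv = sens * n_r / ppv_den if ppv_den > 0 else math.nan
    npv = spec * n_s / npv_den if npv_den > 0 else math.nan
    return {"threshold": float(threshold), "sensitivity": sens,
            "specificity": spec, "accuracy": acc, "plr": plr, "nlr": nlr,
            "ppv": ppv, "npv": npv}


def optimal_threshold(roc: ROCReport) -> float:
    """Threshold maximizing sensitivity + specificity (Youden's J)."""
    j = roc.sensitivity + roc.specificity
    return float(roc.thresholds[int(np.argmax(j))])


def mean_separation(preds_r, preds_s) -> tuple:
    """Difference of class-mean predicted chemosensitivities with a 95% CI.

    Separation = mean(S-class) - mean(R-class).  Each class mean's SE
    combines between-patient variance and the per-patient SEs:
    SE_c^2 = var(means)/n + sum(se_i^2)/n^2; the CI is the difference
    +/- 1.96 * sqrt(SE_R^2 + SE_S^2).  A single-patient class falls back
    to its per-patient SE.
    """
    def stats(preds):
        mus = np.array([p.mean if isinstance(p, PatientPrediction) else p[0]
                        for p in preds])
        ses = np.array([p.se if isinstance(p, PatientPrediction) else p[1]
                        for p in preds])
        if mus.size == 0:
            raise ValueError("both classes must be non-empty")
        if mus.size == 1:
            return mus[0], ses[0]
        var_between = mus.var(ddof=1) / mus.size
        var_within = np.sum(ses**2) / mus.size**2
        return mus.mean(), math.sqrt(var_between + var_within)

    mu_r, se_r = stats(preds_r)
    mu_s, se_s = stats(preds_s)
    diff = float(mu_s - mu_r)
    half = 1.96 * math.sqrt(se_r**2 + se_s**2)
    return diff, (diff - half, diff + half)


def evaluate_predictions(predictions, sigma_floor: float = 0.02) -> ROCReport:
    """Full outcome report from per-patient ensemble predictions."""
    preds_r = [p for p in predictions if p.r_class]
    preds_s = [p for p in predictions if not p.r_class]
    if not preds_r or not preds_s:
        raise ValueError("both R-class and S-class must be represented")
    mix_r = mixture_pdf(preds_r, sigma_floor)
    mix_s = mixture_pdf(preds_s, sigma_floor)
    roc = roc_from_mixture(mix_r, mix_s)
    opt = optimal_threshold(roc)
    roc.fixed = decision_metrics(mix_r, mix_s, len(preds_r), len(preds_s), 0.0)
    roc.optimal = decision_metrics(mix_r, mix_s, len(preds_r), len(preds_s), opt)
    roc.mean_separation, roc.separation_ci = mean_separation(preds_r, preds_s)
    roc.per_patient = list(predictions)
    return roc


def discrete_accuracy(predictions, threshold: float = 0.0) -> float:
    """Fraction of patients whose sign-based assignment matches their class."""
    correct = sum((p.assigned_class(threshold) == "R") == p.r_class
                  for p in predictions)
    return correct / len(predictions)
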