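"""Ensemble of four binary chemosensitivity classifiers.

Each classifier maps a held-out patient's selected-biomarker vector to a
predicted chemosensitivity P in [-1, 1] (negative = resistant phenotype),
and the ensemble reports their mean with a standard error:

1. *Logistic perceptron* -- minimizes the ridge-regularized squared error
   ``sum_p [sigma(b + f_p . w) - y_p]^2 + lambda ||w||^2`` with the
   logistic rescaled to (-1, 1), ``sigma(x) = 2/(1+e^-x) - 1 = tanh(x/2)``,
   so the +/-1 targets are attainable.
2. *Gibbs-relaxation recurrent network* -- relaxes the test vector by
   repeatedly copying single feature values from training vectors drawn
   with probability proportional to their (non-negative) inner product
   with the current state; P is the inner-product-weighted mean label of
   the relaxed vector.
3. *Log-likelihood* -- per-feature Gaussian class densities; the summed
   log-likelihood difference is squashed through sigma for comparability.
4. *Network vote* -- mean label of the k most correlation-contrast-similar
   training patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .similarity import correlation_contrast

__all__ = [
    "TrainingSet",
    "EnsemblePrediction",
    "squashed_logistic",
    "fit_logistic",
    "logistic_classifier",
    "gibbs_rnn_classifier",
    "loglik_classifier",
    "network_classifier",
    "ensemble_predict",
]

CLASSIFIER_NAMES = ("logistic", "rnn", "loglik", "network")


def squashed_logistic(x):
    """Logistic rescaled to (-1, 1): 2/(1+exp(-x)) - 1 = tanh(x/2)."""
    return np.tanh(np.asarray(x, dtype=float) / 2.0)


@dataclass
class TrainingSet:
    """Selected-biomarker training matrix with +/-1 labels."""

    F: np.ndarray  # [n_patients, n_features]
    y: np.ndarray  # +/-1
    ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.F = np.atleast_2d(np.asarray(self.F, dtype=float))
        self.y = np.asarray(self.y, dtype=float)
        if self.F.shape[0] != self.y.size:
            raise ValueError("one label per training vector required")
        if not np.all(np.isin(self.y, (-1.0, 1.0))):
            raise ValueError("labels must be +/-1")
        if not self.ids:
            self.ids = [f"p{i}" for i in range(self.y.size)]

    def require_both_classes(self) -> None:
        if np.unique(self.y).size < 2:
            raise ValueError("training set must contain both classes")

    @property
    def n(self) -> int:
        return int(self.y.size)


# ---------------------------------------------------------------------------
# 1. logistic perceptron


def _logistic_cost_grad(theta: np.ndarray, F: np.ndarray, y: np.ndarray,
                        lam: float) -> tuple:
    b, w = theta[0], theta[1:]
    z = b + F @ w
    s = np.tanh(z / 2.0)
    r = s - y
    cost = float(r @ r + lam * (w @ w))
    dz = r * (1.0 - s * s)  # 2 r * sigma'(z), sigma'(z) = (1 - s^2)/2
    grad = np.empty_like(theta)
    grad[0] = dz.sum()
    grad[1:] = F.T @ dz + 2.0 * lam * w
    return cost, grad


def fit_logistic(train: TrainingSet, lam: float = 0.1, max_iter: int = 20000,
                 tol: float = 1e-8) -> tuple:
    """Deterministic gradient descent with backtracking line search from a
    zero initialization; stops when the gradient norm drops below ``tol``.

    Returns (b, w, converged).
    """
    train.require_both_classes()
    theta = np.zeros(1 + train.F.shape[1])
    step = 1.0
    cost, grad = _logistic_cost_grad(theta, train.F, train.y, lam)
    converged = False
    for _ in range(max_iter):
        gnorm = np.linalg.norm(grad)
        if gnorm < tol:
            converged = True
            break
        # backtracking Armijo line search
        step = min(step * 2.0, 1e3)
        while step > 1e-18:
            trial = theta - step * grad
            c_new, g_new = _logistic_cost_grad(trial, train.F, train.y, lam)
            if c_new <= cost - 1e-4 * step * gnorm**2:
                theta, cost, grad = trial, c_new, g_new
                break
            step /= 2.0
        else:
            break
    if not converged and np.linalg.norm(grad) > 1e3 * tol:
        import warnings

        warnings.warn("logistic fit did not reach the gradient tolerance; "
                      "returning best iterate")
    return float(theta[0]), theta[1:], converged


def logistic_classifier(train: TrainingSet, f_test: np.ndarray,
                        lam: float = 0.1) -> float:
    """P = sigma(b + f_test . w) at the ridge optimum."""
    b, w, _ = fit_logistic(train, lam=lam)
    return float(squashed_logistic(b + np.asarray(f_test, dtype=float) @ w))


# ---------------------------------------------------------------------------
# 2. Gibbs-relaxation recurrent network


def gibbs_rnn_classifier(
    train: TrainingSet,
    f_test: np.ndarray,
    rng: np.random.Generator,
    max_iter: int = 500,
    tol: float = 1e-4,
    window: int = 50,
) -> float:
    """Relax the test vector against the training set by Gibbs sampling.

    Features are mean-centered with the training mean so that inner
    products are informative; negative inner products clamp to zero (they
    are selection probabilities).  At each iteration a training vector p is
    drawn with probability ~ max(f_p . f, 0) and one uniformly chosen
    feature of the working vector is replaced by f_p's value.  The chain
    does not converge pointwise, so the running mean of the working vector
    is the relaxed vector f'; convergence is declared when the running
    mean moves < ``tol`` in max-norm over a ``window``-iteration span.
    P = sum_p y_p (f_p . f') / sum_p (f_p . f') with the same clamped
    weights, so P lies in [-1, 1].
    """
    f_test = np.asarray(f_test, dtype=float)
    mu = train.F.mean(axis=0)
    Fc = train.F - mu
    working = f_test - mu
    n_feat = working.size

    running = working.copy()
    prev_running = running.copy()
    for it in range(1, max_iter + 1):
        weights = np.clip(Fc @ working, 0.0, None)
        total = weights.sum()
        if total <= 0:
            break  # nothing attracts the current state; keep it
        p = rng.choice(train.n, p=weights / total)
        a = int(rng.integers(n_feat))
        working = working.copy()
        working[a] = Fc[p, a]
        running = running + (working - running) / (it + 1)
        if it % window == 0:
            if np.max(np.abs(running - prev_running)) < tol:
                break
            prev_running = running.copy()

    f_prime = running
    weights = np.clip(Fc @ f_prime, 0.0, None)
    if weights.sum() <= 0:
        import warnings

        warnings.warn("Gibbs relaxation found no positive similarities; "
                      "falling back to the unrelaxed vector")
        weights = np.clip(Fc @ (f_test - mu), 0.0, None)
        if weights.sum() <= 0:
            weights = np.ones(train.n)
    return float(train.y @ weights / weights.sum())


# ---------------------------------------------------------------------------
# 3. log-likelihood


def loglik_classifier(train: TrainingSet, f_test: np.ndarray) -> float:
    """Squashed per-feature Gaussian log-likelihood difference.

    For each feature a, L_c(f^a) is the log density of a normal with the
    class-c training mean and (n-1) variance of that feature, the variance
    floored at 1e-6 of the pooled variance; the raw score
    ``sum_a [L_{+1} - L_{-1}]`` is squashed to (-1, 1).
    """
    f_test = np.asarray(f_test, dtype=float)
    pooled = train.F.var(axis=0, ddof=1)
    floor = np.maximum(1e-6 * pooled, 1e-300)
    score = 0.0
    stats = {}
    for c in (-1.0, 1.0):
        rows = train.F[train.y == c]
        if rows.shape[0] < 2:
            raise ValueError("log-likelihood requires >= 2 training members per class")
        var = np.maximum(rows.var(axis=0, ddof=1), floor)
        stats[c] = (rows.mean(axis=0), var)
    for c, sign in ((1.0, +1.0), (-1.0, -1.0)):
        mean, var = stats[c]
        ll = -0.5 * np.sum(np.log(2.0 * np.pi * var) + (f_test - mean) ** 2 / var)
        score += sign * ll
    return float(squashed_logistic(score))


# ---------------------------------------------------------------------------
# 4. network vote


def network_classifier(train: TrainingSet, f_test: np.ndarray, k: int = 3) -> float:
    """Mean label of the k most correlation-contrast-similar training
    patients (ties break by training order)."""
    if k < 1 or k > train.n:
        raise ValueError("k must satisfy 1 <= k <= number of training patients")
    f_test = np.asarray(f_test, dtype=float)
    sims = np.array([correlation_contrast(f_test, fp) for fp in train.F])
    order = sorted(range(train.n), key=lambda j: (-sims[j], j))
    top = order[:k]
    return float(train.y[top].mean())


# ---------------------------------------------------------------------------
# ensemble


@dataclass
class EnsemblePrediction:
    patient_id: str
    per_classifier: dict
    mean: float
    se: float
    failed: list = field(default_factory=list)


def _run_classifiers(train: TrainingSet, f_test: np.ndarray,
                     rng: np.random.Generator, k: int, lam: float) -> tuple:
    values: dict = {}
    failed: list = []
    runners = {
        "logistic": lambda: logistic_classifier(train, f_test, lam=lam),
        "rnn": lambda: gibbs_rnn_classifier(train, f_test, rng),
        "loglik": lambda: loglik_classifier(train, f_test),
        "network": lambda: network_classifier(train, f_test, k=min(k, train.n)),
    }
    for name in CLASSIFIER_NAMES:
        try:
            values[name] = runners[name]()
        except Exception:
            failed.append(name)
    if not values:
        raise RuntimeError("every classifier failed")
    return values, failed


def _stratified_subset(train: TrainingSet, frac: float,
                       rng: np.random.Generator) -> TrainingSet:
    idx: list = []
    for c in (-1.0, 1.0):
        members = np.nonzero(train.y == c)[0]
        n_keep = max(2, int(round(frac * members.size)))
        n_keep = min(n_keep, members.size)
        idx.extend(rng.choice(members, size=n_keep, replace=False))
    idx = sorted(idx)
    return TrainingSet(F=train.F[idx], y=train.y[idx],
                       ids=[train.ids[i] for i in idx])


def ensemble_predict(
    train: TrainingSet,
    f_test: np.ndarray,
    rng: np.random.Generator,
    patient_id: str = "",
    k: int = 3,
    lam: float = 0.1,
    n_resamples: int = 8,
    resample_frac: float = 0.8,
) -> EnsemblePrediction:
    """Ensemble-average chemosensitivity of one held-out patient.

    The mean is over the four classifier outputs; the standard error is
    the across-classifier sample SE (sd / sqrt(4)), with the root-variance
    of ``n_resamples`` stratified 80% training subsets added in quadrature
    when enabled.  A classifier that raises is dropped from the ensemble
    (SE divisor shrinks accordingly) and recorded in ``failed``.
    """
    train.require_both_classes()
    values, failed = _run_classifiers(train, f_test, rng, k, lam)
    preds = np.array([values[n] for n in CLASSIFIER_NAMES if n in values])
    mean = float(preds.mean())
    se = float(preds.std(ddof=1) / np.sqrt(preds.size)) if preds.size > 1 else 0.0

    if n_resamples > 0 and train.n >= 5:
        sub_means = []
        for _ in range(n_resamples):
            sub = _stratified_subset(train, resample_frac, rng)
            try:
                sub_values, _ = _run_classifiers(sub, f_test, rng, k, lam)
            except RuntimeError:
                continue
            sub_means.append(np.mean(list(sub_values.values())))
        if len(sub_means) > 1:
            se = float(np.sqrt(se**2 + np.var(sub_means, ddof=1)))

    return EnsemblePrediction(patient_id=patient_id, per_classifier=values,
                              mean=mean, se=se, failed=failed)
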