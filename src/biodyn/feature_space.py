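"""Orthogonal biomarker construction and z-factor selection.

The 18 spectrogram features per treatment are strongly covariant, so each
treatment block is z-scored over the training patients and decomposed by
SVD into orthonormal components ("BM<i><treatment>").  Components are
ranked by the absolute z-factor

    z = (mean_R - mean_S) / sqrt(var_R + var_S)

of their training scores against the resistant/sensitive split, and the
top ``n_select`` (default 5) across all treatments become the working
feature vectors for the similarity network and the classifiers.
Standardization statistics and loadings are frozen from the training
patients and applied unchanged to held-out, metastatic and test patients;
metastatic data never enter the selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .biomarkers import TREATMENT_CODES

__all__ = ["TreatmentDecomposition", "OrthogonalBiomarkerSet", "z_factor",
           "svd_transform", "select_biomarkers"]


def z_factor(scores: np.ndarray, labels: np.ndarray, resistant_label: int = -1) -> float:
    """Signal-to-noise separation of one component's scores.

    z = (mean_R - mean_S) / sqrt(var_R + var_S) with sample (n-1) variances.
    Requires at least two members per class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    r = scores[labels == resistant_label]
    s = scores[labels != resistant_label]
    if r.size < 2 or s.size < 2:
        raise ValueError("z-factor requires >= 2 members in each class")
    denom = np.sqrt(r.var(ddof=1) + s.var(ddof=1))
    if denom == 0:
        return 0.0 if r.mean() == s.mean() else np.inf * np.sign(r.mean() - s.mean())
    return float((r.mean() - s.mean()) / denom)


@dataclass
class TreatmentDecomposition:
    """Frozen standardization + SVD loadings of one treatment's 18 features."""

    mean: np.ndarray
    std: np.ndarray
    loadings: np.ndarray  # [n_features, n_components], orthonormal columns
    singular_values: np.ndarray
    zero_variance: np.ndarray  # boolean flag per original feature

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean) / self.std @ self.loadings


def svd_transform(X_train: np.ndarray) -> tuple:
    """Fit the standardized SVD on training rows.

    Columns are z-scored over the training patients (zero-variance columns
    are flagged and left unscaled), then decomposed ``Xs = U S V^T``.
    Returns ``(decomposition, training scores)`` with components ordered by
    descending singular value and a deterministic sign convention: the
    largest-magnitude element of each loading column is positive.
    """
    X = np.asarray(X_train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 training patients")
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1)
    zero_var = std == 0
    std = np.where(zero_var, 1.0, std)
    Xs = (X - mean) / std
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    V = Vt.T
    # sign convention for reproducibility
    for k in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
            U[:, k] = -U[:, k]
    dec = TreatmentDecomposition(mean=mean, std=std, loadings=V,
                                 singular_values=S, zero_variance=zero_var)
    return dec, U * S


@dataclass
class OrthogonalBiomarkerSet:
    """Fitted per-treatment decompositions and the selected components."""

    decompositions: dict  # treatment -> TreatmentDecomposition
    selected: list  # [(treatment, component index, z-factor), ...]
    n_select: int
    component_z: dict = field(default_factory=dict)  # treatment -> z array

    @property
    def names(self) -> list:
        return [f"BM{idx + 1}{TREATMENT_CODES[t]}" for t, idx, _ in self.selected]

    def transform(self, blocks: dict) -> np.ndarray:
        """Selected-component scores for patients given per-treatment
        18-feature blocks (arrays [n_patients, 18])."""
        scores = {t: self.decompositions[t].transform(X) for t, X in blocks.items()}
        cols = [scores[t][:, idx] for t, idx, _ in self.selected]
        return np.column_stack(cols)


def select_biomarkers(
    train_blocks: dict,
    train_labels: np.ndarray,
    n_select: int = 5,
    resistant_label: int = -1,
) -> OrthogonalBiomarkerSet:
    """Fit per-treatment SVDs on training patients and pick the top
    ``n_select`` components by |z-factor|.

    ``train_blocks`` maps treatment -> [n_train, 18] spectrogram-feature
    matrix of *training* patients only (the caller must exclude metastatic
    and test patients).  Ties in |z| break by treatment order then
    component index.
    """
    labels = np.asarray(train_labels)
    treatments = list(train_blocks)
    decomps: dict = {}
    component_z: dict = {}
    candidates = []
    for t_order, t in enumerate(treatments):
        dec, scores = svd_transform(train_blocks[t])
        decomps[t] = dec
        zs = np.array([z_factor(scores[:, k], labels, resistant_label)
                       for k in range(scores.shape[1])])
        component_z[t] = zs
        for k, z in enumerate(zs):
            candidates.append((-abs(z), t_order, k, t, float(z)))
    if n_select > len(candidates):
        raise ValueError(
            f"n_select={n_select} exceeds the {len(candidates)} available components"
        )
    candidates.sort()
    selected = [(t, k, z) for _, _, k, t, z in candidates[:n_select]]
    return OrthogonalBiomarkerSet(decompositions=decomps, selected=selected,
                                  n_select=n_select, component_z=component_z)
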