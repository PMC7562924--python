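"""Delimited-text readers and writers for every pipeline artifact.

Tab-separated text is the interchange format throughout: per-well spectra
(long format), cohort manifest, spectrogram matrices (wide format with a
frequency header and a JSON sidecar), feature tables, similarity matrices,
edge lists, prediction tables and the JSON outcome report.  Every writer
has a reader that reconstructs an equal in-memory structure.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import CohortFeatures, PatientPrediction, ROCReport
from .grid import TimeFrequencyGrid
from .similarity import AdjacencyNetwork, SimilarityMatrix
from .spectrogram import DrugResponseSpectrogram
from .synthetic import Cohort, PatientRecord, WellRecord

__all__ = [
    "write_wells_table", "read_wells_table",
    "write_manifest", "read_manifest",
    "write_spectrogram", "read_spectrogram",
    "write_features", "read_features",
    "write_similarity", "read_similarity", "write_edges",
    "write_predictions", "read_predictions",
    "write_report",
]


# ---------------------------------------------------------------------------
# wells + manifest


def write_wells_table(cohort: Cohort, path) -> None:
    """Long-format per-well spectra table (one row per well x loop x
    frequency)."""
    grid = cohort.grid
    rows = []
    for patient in cohort.patients:
        for well in patient.wells:
            viol = ";".join(well.violations)
            for t in range(grid.n_loops):
                for f_idx, f in enumerate(grid.frequencies):
                    rows.append((
                        patient.patient_id, well.well_id, well.treatment,
                        well.immobilization, t, grid.loop_times[t], f,
                        well.spectra[t, f_idx], well.brightness[t], viol,
                        well.speckle_contrast, well.sample_count,
                    ))
    df = pd.DataFrame(rows, columns=[
        "patient_id", "well_id", "treatment", "immobilization", "loop",
        "loop_time_h", "frequency_hz", "spectral_density", "brightness",
        "violations", "speckle_contrast", "sample_count"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_manifest(cohort: Cohort, path) -> None:
    rows = [(p.patient_id, p.clinical_label, p.cohort_tag,
             p.response_phenotype, cohort.seed if cohort.seed is not None else "")
            for p in cohort.patients]
    df = pd.DataFrame(rows, columns=["patient_id", "clinical_label",
                                     "cohort_tag", "response_phenotype", "seed"])
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"patient_id": str})


def read_wells_table(path, manifest_path, dose_loop: int = 4,
                     loop_period: float = 82.0) -> Cohort:
    """Reconstruct a cohort from the wells table and its manifest."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "well_id": str})
    manifest = read_manifest(manifest_path)
    freqs = np.sort(df["frequency_hz"].unique())
    loops = np.sort(df["loop"].unique())
    loop_times = np.sort(df["loop_time_h"].unique())
    grid = TimeFrequencyGrid(frequencies=freqs, loop_times=loop_times,
                             dose_loop=dose_loop, loop_period=loop_period)
    patients = []
    seed = None
    for _, mrow in manifest.iterrows():
        pid = mrow["patient_id"]
        if "seed" in manifest.columns and not pd.isna(mrow.get("seed")):
            try:
                seed = int(mrow["seed"])
            except (TypeError, ValueError):
                seed = None
        patient = PatientRecord(
            patient_id=pid, clinical_label=mrow["clinical_label"],
            cohort_tag=mrow["cohort_tag"],
            response_phenotype=mrow.get("response_phenotype", mrow["clinical_label"]),
        )
        sub = df[df["patient_id"] == pid]
        for well_id, wdf in sub.groupby("well_id", sort=True):
            wdf = wdf.sort_values(["loop", "frequency_hz"])
            spectra = wdf["spectral_density"].to_numpy().reshape(
                loops.size, freqs.size)
            brightness = (wdf.drop_duplicates("loop")
                          .sort_values("loop")["brightness"].to_numpy())
            first = wdf.iloc[0]
            viol = first["violations"]
            violations = [] if pd.isna(viol) or viol == "" else str(viol).split(";")
            patient.wells.append(WellRecord(
                well_id=well_id, patient_id=pid, treatment=first["treatment"],
                spectra=spectra, brightness=brightness, violations=violations,
                immobilization=first["immobilization"],
                speckle_contrast=float(first["speckle_contrast"]),
                sample_count=int(first["sample_count"]),
            ))
        patients.append(patient)
    return Cohort(grid=grid, patients=patients, seed=seed)


# ---------------------------------------------------------------------------
# spectrograms


def write_spectrogram(spgm: DrugResponseSpectrogram, path) -> None:
    """Wide matrix (rows = post-dose loops, columns = frequencies in Hz)
    plus a JSON sidecar with treatment, DQ and grid layout."""
    path = Path(path)
    df = pd.DataFrame(spgm.D, columns=[f"{f:.10g}" for f in spgm.grid.frequencies])
    df.insert(0, "loop_time_h", spgm.grid.post_loop_times)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    meta = {
        "treatment": spgm.treatment,
        "dq": spgm.dq,
        "dose_loop": spgm.grid.dose_loop,
        "loop_period": spgm.grid.loop_period,
        "loop_times": [float(t) for t in spgm.grid.loop_times],
        "baseline": None if spgm.baseline is None else [float(v) for v in spgm.baseline],
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, sort_keys=True, indent=1))


def read_spectrogram(path) -> DrugResponseSpectrogram:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    freqs = np.array([float(c) for c in df.columns[1:]])
    grid = TimeFrequencyGrid(
        frequencies=freqs, loop_times=np.array(meta["loop_times"]),
        dose_loop=meta["dose_loop"], loop_period=meta["loop_period"])
    baseline = None if meta["baseline"] is None else np.array(meta["baseline"])
    return DrugResponseSpectrogram(
        grid=grid, D=df.iloc[:, 1:].to_numpy(), treatment=meta["treatment"],
        dq=meta["dq"], baseline=baseline)


# ---------------------------------------------------------------------------
# features


def write_features(features: CohortFeatures, names, path) -> None:
    df = pd.DataFrame(features.values_matrix, columns=list(names))
    df.insert(0, "patient_id", features.ids)
    df.insert(1, "label", features.labels)
    df.insert(2, "cohort", features.cohort_tags)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_features(path) -> tuple:
    """Returns (CohortFeatures, feature column names)."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    names = [c for c in df.columns if c not in ("patient_id", "label", "cohort")]
    features = CohortFeatures(
        ids=df["patient_id"].tolist(),
        values_matrix=df[names].to_numpy(),
        labels=df["label"].to_numpy(),
        cohort_tags=df["cohort"].tolist(),
    )
    return features, names


# ---------------------------------------------------------------------------
# similarity and network


def write_similarity(sim: SimilarityMatrix, path) -> None:
    df = pd.DataFrame(sim.matrix, columns=sim.ids)
    df.insert(0, "patient_id", sim.ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_similarity(path) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    ids = df["patient_id"].tolist()
    return SimilarityMatrix(ids=ids, matrix=df[df.columns[1:]].to_numpy())


def write_edges(net: AdjacencyNetwork, sim: SimilarityMatrix, path) -> None:
    """Undirected edge list (source, target, similarity)."""
    rows = []
    und = net.undirected
    for i in range(len(net.ids)):
        for j in range(i + 1, len(net.ids)):
            if und[i, j]:
                rows.append((net.ids[i], net.ids[j], sim.matrix[i, j]))
    pd.DataFrame(rows, columns=["source", "target", "similarity"]).to_csv(
        path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# predictions and report


def write_predictions(predictions, path) -> None:
    rows = []
    for p in predictions:
        rows.append((
            p.patient_id, p.cohort_tag, p.label,
            p.per_classifier.get("logistic", math.nan),
            p.per_classifier.get("rnn", math.nan),
            p.per_classifier.get("loglik", math.nan),
            p.per_classifier.get("network", math.nan),
            p.mean, p.se,
        ))
    pd.DataFrame(rows, columns=[
        "patient_id", "cohort", "true_label", "P_logistic", "P_rnn",
        "P_loglik", "P_network", "P_mean", "SE"]).to_csv(
        path, sep="\t", index=False, float_format="%.12g")


def read_predictions(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    preds = []
    for _, row in df.iterrows():
        per = {name: float(row[f"P_{name}"]) for name in
               ("logistic", "rnn", "loglik", "network")
               if not pd.isna(row[f"P_{name}"])}
        preds.append(PatientPrediction(
            patient_id=row["patient_id"], mean=float(row["P_mean"]),
            se=float(row["SE"]), label=int(row["true_label"]),
            cohort_tag=row["cohort"], per_classifier=per))
    return preds


def _jsonable(value):
    if isinstance(value, float) and math.isinf(value):
        return "inf" if value > 0 else "-inf"
    return value


def write_report(report: ROCReport, path) -> None:
    payload = {
        "auc": report.auc,
        "thresholds": {
            "fixed": {k: _jsonable(v) for k, v in report.fixed.items()},
            "optimal": {k: _jsonable(v) for k, v in report.optimal.items()},
        },
        "mean_separation": report.mean_separation,
        "ci": list(report.separation_ci),
        "per_patient": [
            {"patient_id": p.patient_id, "mean": p.mean, "se": p.se,
             "label": p.label, "cohort": p.cohort_tag,
             "r_class": bool(p.r_class),
             "assigned_fixed": p.assigned_class(0.0)}
            for p in report.per_patient
        ],
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


def write_roc_curve(report: ROCReport, path) -> None:
    pd.DataFrame({
        "threshold": report.thresholds,
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
    }).to_csv(path, sep="\t", index=False, float_format="%.8g")
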