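"""End-to-end pipeline: simulate -> spectrograms -> features -> selection
-> classification -> outcome report.

Each stage is an importable function over in-memory objects; ``run_all``
chains them with every intermediate written to disk as delimited text, so
a fixed master seed reproduces byte-identical artifacts.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import io as bio_io
from .biomarkers import (
    assemble_feature_vector,
    feature_names,
    fit_preconditions,
    precondition_deltas,
    project,
    spectrogram_masks,
    UNSTABLE_PRECONDITIONS,
    PRECONDITION_NAMES,
)
from .config import PipelineConfig, stage_rng
from .evaluation import (
    CohortFeatures,
    discrete_accuracy,
    evaluate_predictions,
    loocv,
)
from .feature_space import select_biomarkers
from .similarity import k_neighbor_adjacency, similarity_matrix
from .spectrogram import (
    DQThresholds,
    FluctuationSpectrumSeries,
    assess_data_quality,
    baseline_average,
    cohort_activity_threshold,
    drug_response_spectrogram,
    subtract_control,
    weighted_average_spectrograms,
)
from .synthetic import CONTROL, DRUG_TREATMENTS, Cohort, simulate_cohort

__all__ = ["simulate_stage", "patient_spectrograms", "cohort_features",
           "classify_and_evaluate", "run_all"]


def simulate_stage(config: PipelineConfig, seed: int | None = None) -> Cohort:
    """Simulate the synthetic cohort from the master seed's first substream."""
    seed = config.seed if seed is None else seed
    child = int(np.random.SeedSequence(entropy=int(seed),
                                       spawn_key=(0,)).generate_state(1)[0] % 2**31)
    return simulate_cohort(config.design(), config.phenotype_params(),
                           config.grid(), seed=child)


def _dq_thresholds(cohort: Cohort, config: PipelineConfig) -> DQThresholds:
    all_wells = [w for p in cohort.patients for w in p.wells]
    min_power = cohort_activity_threshold(all_wells, cohort.grid,
                                          fraction=config.low_activity_fraction)
    return DQThresholds(brightness_jump_ratio=config.brightness_jump_ratio,
                        min_band_power=min_power)


def patient_spectrograms(cohort: Cohort, config: PipelineConfig,
                         thresholds: DQThresholds | None = None) -> dict:
    """Replicate-averaged, optionally DMSO-subtracted spectrograms.

    Returns ``{patient_id: {treatment: DrugResponseSpectrogram}}`` for the
    three drug arms (the control arm is consumed by the subtraction), plus
    per-patient precondition inputs under the ``"_precondition"`` key.
    """
    grid = cohort.grid
    if thresholds is None:
        thresholds = _dq_thresholds(cohort, config)

    out: dict = {}
    for patient in cohort.patients:
        arms: dict = {}
        precond: dict = {}
        for treatment in (CONTROL,) + DRUG_TREATMENTS:
            wells = [w for w in patient.wells if w.treatment == treatment]
            if not wells:
                continue
            spgms, dqs = [], []
            base_logs, end_logs = [], []
            bsb_pre, bsb_post, nsd, ncnt = [], [], [], []
            for well in wells:
                series = FluctuationSpectrumSeries.from_well(well, grid)
                dq = assess_data_quality(well, grid, thresholds)
                base = baseline_average(series)
                spgms.append(drug_response_spectrogram(
                    series, base, treatment=treatment, dq=dq))
                dqs.append(dq)
                base_logs.append(np.log10(base))
                end_logs.append(np.log10(well.spectra[-1]))
                bsb_pre.append(well.brightness[:grid.dose_loop].mean())
                bsb_post.append(well.brightness[-1])
                nsd.append(well.speckle_contrast)
                ncnt.append(well.sample_count)
            avg = weighted_average_spectrograms(spgms, dqs)
            arms[treatment] = avg
            w = np.asarray(dqs) / np.sum(dqs)
            precond[treatment] = {
                "baseline": 10.0 ** (w @ np.vstack(base_logs)),
                "endpoint": 10.0 ** (w @ np.vstack(end_logs)),
                "bsb_pre": float(w @ np.asarray(bsb_pre)),
                "bsb_post": float(w @ np.asarray(bsb_post)),
                "nsd": float(w @ np.asarray(nsd)),
                "ncnt": float(w @ np.asarray(ncnt)),
            }
        if config.dmso_subtract and CONTROL in arms:
            control = arms.pop(CONTROL)
            arms = {t: subtract_control(s, control) for t, s in arms.items()}
        else:
            arms.pop(CONTROL, None)
        arms["_precondition"] = precond
        out[patient.patient_id] = arms
    return out


def _drug_block(spgm, precond_inputs, masks, grid, drop_unstable: bool) -> tuple:
    spec_features = project(spgm, masks)
    pre = fit_preconditions(precond_inputs["baseline"], grid,
                            nsd=precond_inputs["nsd"],
                            bsb=precond_inputs["bsb_pre"],
                            ncnt=precond_inputs["ncnt"])
    post = fit_preconditions(precond_inputs["endpoint"], grid,
                             nsd=precond_inputs["nsd"],
                             bsb=precond_inputs["bsb_post"],
                             ncnt=precond_inputs["ncnt"])
    deltas, imputed = precondition_deltas(pre, post)
    if drop_unstable:
        keep = [i for i, n in enumerate(PRECONDITION_NAMES)
                if n not in UNSTABLE_PRECONDITIONS]
        deltas = deltas[keep]
    return np.concatenate([spec_features, deltas]), imputed


def cohort_features(cohort: Cohort, config: PipelineConfig) -> CohortFeatures:
    """81-element feature vectors for every patient in the cohort."""
    grid = cohort.grid
    masks = spectrogram_masks(grid, config.band_edges)
    spgms = patient_spectrograms(cohort, config)
    ids, rows, labels, tags = [], [], [], []
    for patient in cohort.patients:
        arms = spgms[patient.patient_id]
        precond = arms["_precondition"]
        blocks, imputed = {}, {}
        for treatment in DRUG_TREATMENTS:
            block, imp = _drug_block(arms[treatment], precond[treatment],
                                     masks, grid,
                                     config.drop_unstable_preconditions)
            blocks[treatment] = block
            if imp:
                imputed[treatment] = imp
        fv = assemble_feature_vector(
            blocks, patient_id=patient.patient_id, label=patient.y,
            cohort_tag=patient.cohort_tag, imputed=imputed,
            drop_unstable=config.drop_unstable_preconditions)
        ids.append(patient.patient_id)
        rows.append(fv.values)
        labels.append(fv.label)
        tags.append(fv.cohort_tag)
    return CohortFeatures(ids=ids, values_matrix=np.vstack(rows),
                          labels=np.array(labels), cohort_tags=tags)


def classify_and_evaluate(features: CohortFeatures, config: PipelineConfig,
                          seed: int | None = None):
    """LOOCV predictions plus the Gaussian-mixture outcome report."""
    seed = config.seed if seed is None else seed
    rng = stage_rng(seed, "classify")
    preds = loocv(features, rng, n_select=config.n_select, k=config.k,
                  lam=config.lam, n_resamples=config.n_resamples)
    report = evaluate_predictions(preds, sigma_floor=config.sigma_floor)
    return preds, report


def run_all(config: PipelineConfig, seed: int | None = None,
            out_dir=None) -> dict:
    """Run every stage, writing each stage's artifacts under ``out_dir``.

    Returns a dict of output paths plus the in-memory report.  The same
    seed and config produce byte-identical numeric outputs.
    """
    seed = config.seed if seed is None else seed
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = simulate_stage(config, seed)
    bio_io.write_wells_table(cohort, out / "wells.tsv")
    bio_io.write_manifest(cohort, out / "manifest.tsv")

    spgm_dir = out / "spectrograms"
    spgm_dir.mkdir(exist_ok=True)
    spgms = patient_spectrograms(cohort, config)
    for pid, arms in spgms.items():
        for treatment in DRUG_TREATMENTS:
            bio_io.write_spectrogram(arms[treatment],
                                     spgm_dir / f"{pid}.{treatment}.tsv")

    features = cohort_features(cohort, config)
    names = feature_names(config.drop_unstable_preconditions)
    bio_io.write_features(features, names, out / "features.tsv")

    # selection + similarity network on the full training cohort
    train_idx = features.training_indices
    from .evaluation import _treatment_blocks  # shared block slicing

    selector = select_biomarkers(_treatment_blocks(features, train_idx),
                                 features.labels[train_idx],
                                 n_select=config.n_select)
    all_blocks = _treatment_blocks(features, np.arange(len(features.ids)))
    selected = selector.transform(all_blocks)
    import pandas as pd

    sel_df = pd.DataFrame(selected, columns=selector.names)
    sel_df.insert(0, "patient_id", features.ids)
    sel_df.insert(1, "label", features.labels)
    sel_df.insert(2, "cohort", features.cohort_tags)
    sel_df.to_csv(out / "selected.tsv", sep="\t", index=False,
                  float_format="%.12g")

    groups = {pid: ("metastatic" if tag == "metastatic"
                    else ("resistant" if lbl == -1 else "sensitive"))
              for pid, tag, lbl in zip(features.ids, features.cohort_tags,
                                       features.labels)}
    sim = similarity_matrix(selected, features.ids, groups=groups)
    net = k_neighbor_adjacency(sim, k=min(config.k, len(sim.ids) - 1))
    bio_io.write_similarity(sim, out / "similarity.tsv")
    bio_io.write_edges(net, sim, out / "edges.tsv")

    preds, report = classify_and_evaluate(features, config, seed)
    bio_io.write_predictions(preds, out / "predictions.tsv")
    bio_io.write_report(report, out / "report.json")
    bio_io.write_roc_curve(report, out / "roc_curve.tsv")

    return {
        "out_dir": out,
        "report": report,
        "predictions": preds,
        "accuracy_fixed": discrete_accuracy(preds),
        "paths": {name: out / name for name in
                  ("wells.tsv", "manifest.tsv", "features.tsv", "selected.tsv",
                   "similarity.tsv", "edges.tsv", "predictions.tsv",
                   "report.json", "roc_curve.tsv")},
    }
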