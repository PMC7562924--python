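#!/usr/bin/env python
"""Ensemble classification with LOOCV and the Gaussian-mixture ROC report.

Predicts every training patient by leave-one-out cross-validation (feature
selection refit per fold) and every metastatic specimen with the full
training model, builds the R-class/S-class Gaussian-mixture PDFs, sweeps the
ROC, and reports accuracy, sensitivity, specificity, likelihood ratios and
the class mean separation at the fixed (zero) and optimal thresholds.
Writes predictions.tsv, report.json, roc_curve.tsv and three figures.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from biodyn import PipelineConfig
from biodyn import io as bio_io
from biodyn.evaluation import discrete_accuracy, mixture_pdf
from biodyn.pipeline import classify_and_evaluate


def _figures(preds, report, out: Path) -> None:
    # per-patient ensemble predictions with error bars
    order = sorted(range(len(preds)),
                   key=lambda i: (not preds[i].r_class,
                                  preds[i].cohort_tag != "metastatic",
                                  preds[i].mean))
    fig, ax = plt.subplots(figsize=(8, 3.2))
    xs = np.arange(len(preds))
    means = [preds[i].mean for i in order]
    ses = [preds[i].se for i in order]
    colors = ["#8b0000" if preds[i].cohort_tag == "metastatic"
              else ("#d95f02" if preds[i].label == -1 else "#1f78b4")
              for i in order]
    ax.bar(xs, means, yerr=ses, color=colors, capsize=2)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xticks(xs, [preds[i].patient_id for i in order],
                  rotation=90, fontsize=6)
    ax.set_ylabel("predicted chemosensitivity")
    fig.tight_layout()
    fig.savefig(out / "fig_predictions.png", dpi=150)

    # class mixture PDFs
    mix_r = mixture_pdf([p for p in preds if p.r_class])
    mix_s = mixture_pdf([p for p in preds if not p.r_class])
    x = np.linspace(-1.6, 1.6, 801)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(x, mix_r.pdf(x), label="R-class", color="#d95f02")
    ax.plot(x, mix_s.pdf(x), label="S-class", color="#1f78b4")
    ax.axvline(0, color="b", ls="--", lw=0.8)
    ax.axvline(report.optimal["threshold"], color="r", ls="--", lw=0.8)
    ax.set_xlabel("predicted chemosensitivity")
    ax.set_ylabel("PDF")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "fig_mixture_pdf.png", dpi=150)

    # ROC
    fig, ax = plt.subplots(figsize=(3.6, 3.6))
    ax.plot(1 - report.specificity, report.sensitivity, color="k")
    for key, color in (("fixed", "b"), ("optimal", "r")):
        m = getattr(report, key)
        ax.plot(1 - m["specificity"], m["sensitivity"], "o", color=color,
                label=f"{key} (acc {m['accuracy']:.2f})")
    ax.plot([0, 1], [0, 1], ":", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "fig_roc.png", dpi=150)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = PipelineConfig(seed=args.seed)
    feats, _ = bio_io.read_features(args.out / "features.tsv")
    preds, report = classify_and_evaluate(feats, cfg)
    bio_io.write_predictions(preds, args.out / "predictions.tsv")
    bio_io.write_report(report, args.out / "report.json")
    bio_io.write_roc_curve(report, args.out / "roc_curve.tsv")
    _figures(preds, report, args.out)

    met = [p for p in preds if p.cohort_tag == "metastatic"]
    print(f"LOOCV discrete accuracy (threshold 0): {discrete_accuracy(preds):.3f}")
    print(f"mixture AUC: {report.auc:.3f}")
    lo, hi = report.separation_ci
    print(f"mean class separation: {report.mean_separation:.2f} "
          f"(95% CI {lo:.2f}-{hi:.2f})")
    for key in ("fixed", "optimal"):
        m = getattr(report, key)
        print(f"{key:>8} threshold {m['threshold']:+.3f}: "
              f"sens {m['sensitivity']:.2f} spec {m['specificity']:.2f} "
              f"acc {m['accuracy']:.2f} PLR {m['plr']:.1f} NLR {m['nlr']:.2f} "
              f"PPV {m['ppv']:.2f} NPV {m['npv']:.2f}")
    print(f"metastatic specimens assigned R-class: "
          f"{sum(p.assigned_class() == 'R' for p in met)}/{len(met)}")


if __name__ == "__main__":
    main()
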