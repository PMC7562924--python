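#!/usr/bin/env python
"""Orthogonalize the spectrogram biomarkers and select the top components.

Per treatment arm, the 18 spectrogram features of the *training* patients
are z-scored and decomposed by SVD; components are ranked by |z-factor|
(resistant vs sensitive separation) and the top 5 across arms become the
working feature vectors.  Metastatic specimens never enter the selection.
Writes results/selected.tsv and results/loadings.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from biodyn import PipelineConfig
from biodyn import io as bio_io
from biodyn.evaluation import _treatment_blocks
from biodyn.feature_space import select_biomarkers


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = PipelineConfig()
    feats, _ = bio_io.read_features(args.out / "features.tsv")
    train_idx = feats.training_indices
    sel = select_biomarkers(_treatment_blocks(feats, train_idx),
                            feats.labels[train_idx], n_select=cfg.n_select)

    selected = sel.transform(_treatment_blocks(feats,
                                               np.arange(len(feats.ids))))
    df = pd.DataFrame(selected, columns=sel.names)
    df.insert(0, "patient_id", feats.ids)
    df.insert(1, "label", feats.labels)
    df.insert(2, "cohort", feats.cohort_tags)
    df.to_csv(args.out / "selected.tsv", sep="\t", index=False,
              float_format="%.12g")

    rows = []
    for (treatment, comp, z), name in zip(sel.selected, sel.names):
        loadings = sel.decompositions[treatment].loadings[:, comp]
        rows.append([name, treatment, comp + 1, z] + list(loadings))
    pd.DataFrame(rows, columns=["component", "treatment", "index", "z_factor"]
                 + [f"w{i}" for i in range(18)]).to_csv(
        args.out / "loadings.tsv", sep="\t", index=False, float_format="%.6g")

    print("selected components (|z-factor| ranked, training patients only):")
    for (treatment, comp, z), name in zip(sel.selected, sel.names):
        print(f"  {name:>12}  z = {z:+.2f}")
    print(f"wrote {args.out / 'selected.tsv'} and {args.out / 'loadings.tsv'}")


if __name__ == "__main__":
    main()
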