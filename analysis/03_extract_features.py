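#!/usr/bin/env python
"""Extract the 81-element patient feature vectors.

Projects each drug-response spectrogram onto the 9 global + 9 local filter
masks and appends the 9 drug-induced precondition changes per treatment arm.
Writes results/features.tsv (patient_id, label, cohort + 81 named columns).
"""

import argparse
from pathlib import Path

from biodyn import PipelineConfig
from biodyn import io as bio_io
from biodyn.biomarkers import feature_names
from biodyn.pipeline import cohort_features


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = PipelineConfig()
    cohort = bio_io.read_wells_table(args.out / "wells.tsv",
                                     args.out / "manifest.tsv")
    feats = cohort_features(cohort, cfg)
    bio_io.write_features(feats, feature_names(), args.out / "features.tsv")
    print(f"extracted {feats.values_matrix.shape[1]} features "
          f"(3 drugs x (18 spectrogram + 9 precondition)) for "
          f"{len(feats.ids)} patients -> {args.out / 'features.tsv'}")


if __name__ == "__main__":
    main()
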