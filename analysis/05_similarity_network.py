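#!/usr/bin/env python
"""Correlation-contrast similarity matrix and the k = 3 neighbor network.

Builds all pairwise correlation contrasts between the selected feature
vectors, display-ordered resistant -> metastatic -> sensitive with
average-linkage clustering within each group, and links each patient to its
3 most similar peers.  Reports the within-class vs between-class similarity
contrast (the block-diagonal structure) and where the metastatic specimens
attach.  Writes results/similarity.tsv and results/edges.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from biodyn import PipelineConfig, k_neighbor_adjacency, similarity_matrix
from biodyn import io as bio_io


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = PipelineConfig()
    df = pd.read_csv(args.out / "selected.tsv", sep="\t",
                     dtype={"patient_id": str})
    ids = df["patient_id"].tolist()
    vectors = df[[c for c in df.columns
                  if c.startswith("BM")]].to_numpy()
    groups = {row.patient_id: ("metastatic" if row.cohort == "metastatic"
                               else ("resistant" if row.label == -1
                                     else "sensitive"))
              for row in df.itertuples()}

    sim = similarity_matrix(vectors, ids, groups=groups)
    net = k_neighbor_adjacency(sim, k=cfg.k)
    bio_io.write_similarity(sim, args.out / "similarity.tsv")
    bio_io.write_edges(net, sim, args.out / "edges.tsv")

    rclass = [i for i, pid in enumerate(sim.ids)
              if groups[pid] in ("resistant", "metastatic")]
    sclass = [i for i, pid in enumerate(sim.ids) if groups[pid] == "sensitive"]
    within = np.concatenate([
        sim.matrix[np.ix_(rclass, rclass)][np.triu_indices(len(rclass), 1)],
        sim.matrix[np.ix_(sclass, sclass)][np.triu_indices(len(sclass), 1)]])
    between = sim.matrix[np.ix_(rclass, sclass)].ravel()
    print(f"mean within-class similarity:  {within.mean():+.3f}")
    print(f"mean between-class similarity: {between.mean():+.3f}")

    met = [pid for pid in sim.ids if groups[pid] == "metastatic"]
    und = net.undirected
    for pid in met:
        i = net.ids.index(pid)
        neigh = [net.ids[j] for j in np.nonzero(und[i])[0]]
        kinds = {g: sum(groups[n] == g for n in neigh)
                 for g in ("resistant", "metastatic", "sensitive")}
        print(f"metastatic {pid}: neighbors {neigh} "
              f"(R {kinds['resistant']}, M {kinds['metastatic']}, "
              f"S {kinds['sensitive']})")
    print(f"wrote {args.out / 'similarity.tsv'} and {args.out / 'edges.tsv'}")


if __name__ == "__main__":
    main()
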