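#!/usr/bin/env python
"""Cluster enrichment, k-NN tissue mixing and label-transfer filtering.

Tests IgA1 enrichment in the tumour-associated cluster by label
permutation (10,000 shuffles), scores each cell's neighbourhood for
tumour origin (k = 200), and filters cells to the top quartile of
label-transfer confidence.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from seroclone import (io, knn_tissue_score, label_transfer_confidence,
                       permutation_enrichment)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 2026


def main() -> None:
    cells = io.read_repertoire(RESULTS / "data" / "repertoire_cells.tsv")
    cells = cells.assign(dominant_isotype=cells["c_call"])
    scores = pd.read_csv(RESULTS / "data" / "label_transfer_scores.csv")

    cluster = int(cells["cluster"].max())
    out = {}
    for attribute in ("IGHA1", "IGHA2"):
        enr = permutation_enrichment(cells, cluster, attribute,
                                     n_perm=10_000, seed=SEED + 3)
        out[attribute] = {"log2_fold": enr.log2_fold, "p": enr.p_empirical,
                          "observed_proportion": enr.observed_proportion}
        print(f"cluster {cluster} {attribute}: log2 fold = {enr.log2_fold:.2f}, "
              f"permutation p = {enr.p_empirical:.2e}")

    knn = knn_tissue_score(cells[["umap_1", "umap_2"]].to_numpy(),
                           cells["tissue"].to_numpy(), "tumour", k=200)
    np.savetxt(RESULTS / "knn_tumour_score.csv", knn, delimiter=",",
               header="score", comments="")
    by_cluster = (pd.Series(knn).groupby(cells["cluster"]).mean())
    print("mean k-NN tumour score by cluster:",
          {int(k): round(v, 3) for k, v in by_cluster.items()})
    out["knn"] = {"global_tumour_fraction": float((cells.tissue == "tumour").mean()),
                  "max_cluster_mean_score": float(by_cluster.max())}

    conf = label_transfer_confidence(scores.drop(columns="cell_id").to_numpy(),
                                     labels=list(scores.columns[1:]))
    kept = conf["keep_top_quartile"].mean()
    print(f"label-transfer filter keeps {100 * kept:.1f}% of cells "
          f"(top quartile of max - second-max prediction score)")
    out["label_transfer_kept_fraction"] = float(kept)

    (RESULTS / "cluster_enrichment.json").write_text(
        json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
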