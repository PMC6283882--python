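#!/usr/bin/env python
"""Hierarchical clustering of correlation signatures across strata: each
group (and the HD sex/age strata) contributes per-analyte correlation
profiles which are clustered jointly (1 - Pearson distance, average
linkage) and rendered as a clustered heatmap."""

from pathlib import Path

import pandas as pd

from aabnet import StratumSpec, read_cohort_table, stratify
from aabnet.clustering import build_signature_matrix, clustered_heatmap, hcluster

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = read_cohort_table(OUT / "cohort.csv")
    strata = [(g, table.select_groups([g])) for g in table.groups]
    # healthy donors additionally split by sex and the 65-year dichotomy
    hd = table.select_groups(["HD"])
    for label, sub in stratify(hd, StratumSpec("sex")):
        if sub.n_subjects >= 10:
            strata.append((f"HD_{label}", sub))
    for label, sub in stratify(hd, StratumSpec("age65")):
        if sub.n_subjects >= 10:
            strata.append((f"HD_{label}", sub))

    sig = build_signature_matrix(strata, method="pearson")
    dendro = hcluster(sig)
    order = [sig.row_labels[i] for i in dendro.leaf_order]
    pd.DataFrame(order, columns=["stratum", "analyte"]).to_csv(
        OUT / "cluster_leaf_order.csv", index=False)
    (OUT / "cluster_dendrogram.nwk").write_text(dendro.to_newick())
    clustered_heatmap(sig, str(OUT / "signature_heatmap.png"))
    cut = dendro.cut(4)
    frame = pd.DataFrame(sig.row_labels, columns=["stratum", "analyte"])
    frame["cluster"] = cut
    frame.to_csv(OUT / "cluster_k4.csv", index=False)
    print(f"clustered {len(sig.row_labels)} signature rows from "
          f"{len(strata)} strata; k=4 cluster sizes: "
          f"{frame['cluster'].value_counts().sort_index().tolist()}")


if __name__ == "__main__":
    main()
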