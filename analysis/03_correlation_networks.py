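#!/usr/bin/env python
"""Spearman correlation networks per group (edges at rho > 0.6) and
edge-set comparisons against the healthy-donor network."""

from pathlib import Path

import pandas as pd

from aabnet import build_network, compare_networks, correlation_matrix, read_cohort_table
from aabnet.networks import circle_plot

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = read_cohort_table(OUT / "cohort.csv")
    nets = {}
    for group in table.groups:
        corr = correlation_matrix(table.select_groups([group]), method="spearman")
        corr.values.to_csv(OUT / f"correlation_{group}.csv")
        net = build_network(corr, threshold=0.6)
        net.edge_list().to_csv(OUT / f"edges_{group}.tsv", sep="\t", index=False)
        circle_plot(net, OUT / f"network_{group}.png", title=group)
        nets[group] = net
        print(f"{group}: {len(net.edges)} edges > 0.6")
    rows = []
    for group in ("SSc", "OC", "AD"):
        res = compare_networks(nets["HD"], nets[group])
        rows.append({"comparison": f"HD_vs_{group}", "jaccard": res["jaccard"],
                     "lost": ";".join("-".join(e) for e in res["lost"]),
                     "gained": ";".join("-".join(e) for e in res["gained"])})
        print(f"HD vs {group}: jaccard={res['jaccard']:.3f}, lost={res['lost']}")
    pd.DataFrame(rows).to_csv(OUT / "network_comparison.csv", index=False)


if __name__ == "__main__":
    main()
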