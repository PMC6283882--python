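"""Correlation matrices, threshold networks, and network comparison.

Spearman rank (default) or Pearson product-moment correlations are computed
pairwise-complete per analyte pair; a cell is set missing when fewer than
``min_n`` subjects have both analytes observed.  Networks keep an edge when
the correlation strictly exceeds the threshold (default 0.6, signed rule),
the convention used for circle-plot renderings where only correlations
above the cutoff are drawn and line width encodes the strength of the
association.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import CohortTable

DEFAULT_THRESHOLD = 0.6
DEFAULT_MIN_N = 10


@dataclass
class CorrelationMatrix:
    """Symmetric analyte x analyte correlation matrix with per-cell n."""

    values: pd.DataFrame
    n_pairs: pd.DataFrame
    method: str  # spearman | pearson

    @property
    def analytes(self) -> list[str]:
        return list(self.values.columns)

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("correlation matrix must be symmetric")
        finite = v[np.isfinite(v)]
        if finite.size and np.max(np.abs(finite)) > 1 + 1e-10:
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class AabNetwork:
    """Undirected threshold graph over analytes; isolated nodes retained."""

    graph: nx.Graph
    threshold: float
    rule: str  # signed | absolute

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"analyte_a": a, "analyte_b": b, "weight": d["weight"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["analyte_a", "analyte_b", "weight"])


def correlation_matrix(
    table: CohortTable,
    method: str = "spearman",
    min_n: int = DEFAULT_MIN_N,
) -> CorrelationMatrix:
    """Pairwise-complete correlation matrix of a cohort's analytes.

    Spearman uses midranks for ties.  Cells whose pairwise-complete sample
    size falls below ``min_n`` are set missing.
    """
    if method not in {"spearman", "pearson"}:
        raise ValueError("method must be spearman or pearson")
    if table.n_subjects < min_n:
        raise ValueError(
            f"table has {table.n_subjects} subjects; need at least min_n={min_n}"
        )
    vals = table.values
    corr = vals.corr(method=method, min_periods=max(min_n, 2))
    notna = vals.notna().astype(int)
    n_pairs = notna.T @ notna
    corr = corr.mask(n_pairs < min_n)
    np.fill_diagonal(corr.values, 1.0)
    return CorrelationMatrix(values=corr, n_pairs=n_pairs, method=method)


def build_network(
    corr: CorrelationMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    rule: str = "signed",
) -> AabNetwork:
    """Threshold graph: edge iff rho > threshold (signed, default) or
    |rho| > threshold (absolute).  Missing cells never produce edges."""
    if not (0 <= threshold < 1):
        raise ValueError("threshold must lie in [0, 1)")
    if rule not in {"signed", "absolute"}:
        raise ValueError("rule must be signed or absolute")
    g = nx.Graph()
    g.add_nodes_from(corr.analytes)
    v = corr.values
    for i, a in enumerate(corr.analytes):
        for b in corr.analytes[i + 1:]:
            rho = v.loc[a, b]
            if pd.isna(rho):
                continue
            strength = abs(rho) if rule == "absolute" else rho
            if strength > threshold:
                g.add_edge(a, b, weight=float(rho))
    return AabNetwork(graph=g, threshold=threshold, rule=rule)


def family_correlogram(
    corr: CorrelationMatrix, families: Mapping[str, Sequence[str]]
) -> dict[str, pd.DataFrame]:
    """Sub-correlograms for named receptor families, order preserved."""
    out = {}
    for name, members in families.items():
        missing = [m for m in members if m not in corr.values.columns]
        if missing:
            raise ValueError(f"family {name!r}: unknown analyte(s) {missing}")
        out[name] = corr.values.loc[list(members), list(members)]
    return out


def compare_networks(a: AabNetwork, b: AabNetwork) -> dict:
    """Edge-set comparison: Jaccard similarity plus lost/gained edges
    (relative to ``a``).  Jaccard is 1 when both edge sets are empty."""
    if set(a.nodes) != set(b.nodes):
        raise ValueError("networks must share the node set")
    ea, eb = a.edges, b.edges
    union = ea | eb
    jaccard = 1.0 if not union else len(ea & eb) / len(union)
    fmt = lambda es: sorted(tuple(sorted(e)) for e in es)
    return {"jaccard": jaccard, "lost": fmt(ea - eb), "gained": fmt(eb - ea)}


# ---------------------------------------------------------------------------
# Export / rendering
# ---------------------------------------------------------------------------

def write_graphml(network: AabNetwork, path: str | Path) -> Path:
    path = Path(path)
    nx.write_graphml(network.graph, path)
    return path


def circle_plot(network: AabNetwork, path: str | Path, title: str | None = None) -> Path:
    """Circular-layout plot with line width proportional to correlation."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(7, 7))
    pos = nx.circular_layout(network.graph)
    weights = [abs(d["weight"]) for _, _, d in network.graph.edges(data=True)]
    nx.draw_networkx_nodes(network.graph, pos, ax=ax, node_size=350, node_color="#c6dbef")
    nx.draw_networkx_labels(network.graph, pos, ax=ax, font_size=7)
    nx.draw_networkx_edges(
        network.graph, pos, ax=ax, width=[4 * w for w in weights], alpha=0.6
    )
    ax.set_title(title or f"correlations > {network.threshold}")
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
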