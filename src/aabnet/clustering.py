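"""Hierarchical clustering of correlation signatures.

A signature matrix stacks, per stratum (e.g. HD females, HD males, a disease
group), each analyte's within-stratum correlation profile: rows are
(stratum, analyte) pairs, columns are analytes.  Rows are clustered with
distance 1 - Pearson correlation between profiles and average linkage by
default, so analytes whose correlation *patterns* agree — within or across
strata — merge early, reproducing the module structure seen in clustered
correlogram heatmaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .cohort import CohortTable
from .networks import correlation_matrix

logger = logging.getLogger(__name__)

#: Heatmap color ranges used for rendering (value range of the color bar).
HEATMAP_RANGE_SIGNATURE = (-0.6, 0.9)
HEATMAP_RANGE_CORRELATION = (0.0, 1.0)


@dataclass
class SignatureMatrix:
    """Rows: (stratum, analyte) correlation profiles; columns: analytes."""

    values: pd.DataFrame  # MultiIndex rows (stratum, analyte)

    @property
    def row_labels(self) -> list[tuple[str, str]]:
        return list(self.values.index)

    @property
    def analytes(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over signature rows."""

    linkage_matrix: np.ndarray  # scipy linkage format
    labels: list
    linkage: str
    distance: str

    @property
    def leaf_order(self) -> list[int]:
        if len(self.labels) == 1:
            return [0]
        return hierarchy.leaves_list(self.linkage_matrix).tolist()

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2] if self.linkage_matrix.size else np.array([])

    def cut(self, k: int) -> np.ndarray:
        """Flat cluster labels (1..k) at k clusters, in input row order."""
        if len(self.labels) == 1:
            return np.array([1])
        return hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")

    def to_newick(self) -> str:
        if len(self.labels) == 1:
            return f"{self.labels[0]};"
        tree = hierarchy.to_tree(self.linkage_matrix)

        def _fmt(node) -> str:
            if node.is_leaf():
                name = self.labels[node.id]
                if isinstance(name, tuple):
                    name = "|".join(map(str, name))
                return str(name).replace(" ", "_")
            left, right = _fmt(node.left), _fmt(node.right)
            dl = max(node.dist - node.left.dist, 0.0)
            dr = max(node.dist - node.right.dist, 0.0)
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return _fmt(tree) + ";"


def build_signature_matrix(
    strata: list[tuple[str, CohortTable]],
    method: str = "pearson",
    min_n: int = 10,
) -> SignatureMatrix:
    """Stack per-stratum correlation rows into a signature matrix.

    Each stratum contributes its full analyte x analyte correlation matrix;
    row labels carry the stratum so disease and demographic strata can be
    clustered jointly against the same analyte columns.
    """
    blocks = []
    for label, table in strata:
        if table.n_subjects < min_n:
            raise ValueError(
                f"stratum {label!r} has {table.n_subjects} subjects (< min_n={min_n})"
            )
        corr = correlation_matrix(table, method=method, min_n=min_n)
        block = corr.values.copy()
        block.index = pd.MultiIndex.from_product(
            [[label], block.index], names=["stratum", "analyte"]
        )
        blocks.append(block)
    return SignatureMatrix(values=pd.concat(blocks))


def _impute(values: pd.DataFrame, max_row_missing: float = 0.2) -> pd.DataFrame:
    """Mean-impute missing cells per column; drop rows > 20% missing."""
    frac = values.isna().mean(axis=1)
    dropped = values.index[frac > max_row_missing]
    if len(dropped):
        logger.warning("dropping %d signature row(s) with >%.0f%% missing",
                       len(dropped), 100 * max_row_missing)
    kept = values.drop(index=dropped)
    n_missing = int(kept.isna().sum().sum())
    if n_missing:
        logger.info("mean-imputing %d missing signature cell(s)", n_missing)
        kept = kept.fillna(kept.mean(axis=0))
    return kept


def hcluster(
    matrix: SignatureMatrix | pd.DataFrame,
    linkage: str = "average",
    distance: str = "one-minus-pearson",
    impute: bool = False,
) -> Dendrogram:
    """Agglomerative clustering of signature rows.

    distance "one-minus-pearson" is 1 - Pearson correlation between row
    profiles (shift-invariant per row); "euclidean" is the plain L2 metric.
    Missing cells raise unless ``impute=True`` (per-column mean imputation,
    rows with > 20% missing dropped).
    """
    values = matrix.values if isinstance(matrix, SignatureMatrix) else matrix
    if values.isna().any().any():
        if not impute:
            raise ValueError("signature matrix has missing cells; pass impute=True")
        values = _impute(values)
    if len(values) < 1:
        raise ValueError("need at least one signature row")
    labels = list(values.index)
    if len(values) == 1:
        return Dendrogram(np.empty((0, 4)), labels, linkage, distance)
    X = values.to_numpy(dtype=float)
    if distance == "one-minus-pearson":
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(X)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        dist = np.clip(1.0 - corr, 0.0, None)
        dist = (dist + dist.T) / 2
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
    elif distance == "euclidean":
        from scipy.spatial.distance import pdist
        condensed = pdist(X)
    else:
        raise ValueError("distance must be one-minus-pearson or euclidean")
    if linkage == "ward" and distance != "euclidean":
        raise ValueError("ward linkage requires euclidean distance")
    Z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(Z, labels, linkage, distance)


def cluster_agreement(dendro: Dendrogram, k: int, truth) -> float:
    """Adjusted Rand index between the k-cluster cut and reference labels."""
    if k < 2:
        raise ValueError("need k >= 2 clusters")
    truth = np.asarray(truth)
    cut = dendro.cut(k)
    if truth.shape[0] != cut.shape[0]:
        raise ValueError(
            f"truth has {truth.shape[0]} labels for {cut.shape[0]} rows"
        )
    return float(adjusted_rand_score(truth, cut))


def clustered_heatmap(
    matrix: SignatureMatrix | pd.DataFrame,
    path: str,
    linkage: str = "average",
    distance: str = "one-minus-pearson",
    value_range: tuple[float, float] = HEATMAP_RANGE_SIGNATURE,
    impute: bool = False,
) -> str:
    """Heatmap with row/column dendrogram ordering written to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = matrix.values if isinstance(matrix, SignatureMatrix) else matrix
    rows = hcluster(values, linkage=linkage, distance=distance, impute=impute)
    cols = hcluster(values.T, linkage=linkage, distance=distance, impute=impute)
    ordered = values.iloc[rows.leaf_order, cols.leaf_order]
    fig, ax = plt.subplots(figsize=(8, max(4, 0.18 * len(values))))
    im = ax.imshow(ordered.to_numpy(), vmin=value_range[0], vmax=value_range[1],
                   cmap="viridis", aspect="auto")
    ax.set_xticks(range(ordered.shape[1]), ordered.columns, rotation=90, fontsize=6)
    row_names = ["|".join(map(str, r)) if isinstance(r, tuple) else str(r)
                 for r in ordered.index]
    ax.set_yticks(range(ordered.shape[0]), row_names, fontsize=5)
    fig.colorbar(im, ax=ax, label="correlation")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
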