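"""Fisher linear discriminant analysis of global antibody signatures.

Axes solve the generalized eigenproblem S_B v = lambda S_W v with the
within-class scatter shrunk toward its diagonal,

    S_W(s) = (1 - s) * S_W + s * diag(S_W),

which keeps the problem well posed when the panel width approaches the group
sizes.  Analytes are z-scored before fitting by default.  Separation is
quantified by stratified k-fold nearest-centroid accuracy in discriminant
space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.model_selection import StratifiedKFold

from .cohort import CohortTable

DEFAULT_SHRINKAGE = 0.1


@dataclass
class LdaModel:
    directions: np.ndarray       # (p, r) unit-norm discriminant axes
    eigenvalues: np.ndarray      # (r,) between/within variance ratios, desc
    class_means: pd.DataFrame    # group x analyte centroids, original units
    classes: list[str]
    shrinkage: float
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    analytes: list[str]

    def transform(self, values: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = values.to_numpy(dtype=float) if isinstance(values, pd.DataFrame) else np.asarray(values, dtype=float)
        Xz = (X - self.scaler_mean) / self.scaler_sd
        return Xz @ self.directions

    def centroids(self) -> np.ndarray:
        """Class centroids in discriminant space."""
        return self.transform(self.class_means)


def _scatter_matrices(X: np.ndarray, y: np.ndarray, classes: list[str]):
    p = X.shape[1]
    grand = X.mean(axis=0)
    S_W = np.zeros((p, p))
    S_B = np.zeros((p, p))
    for c in classes:
        Xc = X[y == c]
        mean_c = Xc.mean(axis=0)
        d = Xc - mean_c
        S_W += d.T @ d
        diff = (mean_c - grand)[:, None]
        S_B += Xc.shape[0] * (diff @ diff.T)
    S_W /= max(X.shape[0] - len(classes), 1)
    S_B /= max(len(classes) - 1, 1)
    return S_W, S_B


def fit_lda(
    table: CohortTable,
    label: str = "group",
    shrinkage: float = DEFAULT_SHRINKAGE,
    standardize: bool = True,
) -> LdaModel:
    """Fit Fisher LDA on a cohort's analyte panel.

    Keeps at most min(p, g-1) axes; eigenvalues are the between/within
    variance ratios in non-increasing order.  Sign convention: each axis's
    largest-magnitude loading is positive.
    """
    y = table.meta[label].to_numpy()
    classes = sorted(pd.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("need at least two groups")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"group {c!r} has fewer than 2 subjects")
    if table.values.isna().any().any():
        raise ValueError("missing cells present; impute or drop upstream")
    X = table.values.to_numpy(dtype=float)
    if standardize:
        mean, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
    else:
        mean, sd = np.zeros(X.shape[1]), np.ones(X.shape[1])
    Xz = (X - mean) / sd

    S_W, S_B = _scatter_matrices(Xz, y, classes)
    S_W_reg = (1.0 - shrinkage) * S_W + shrinkage * np.diag(np.diag(S_W))
    try:
        evals, evecs = linalg.eigh(S_B, S_W_reg)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "within-class scatter is singular; increase shrinkage"
        ) from exc
    order = np.argsort(evals)[::-1]
    r = min(X.shape[1], len(classes) - 1)
    evals = np.clip(evals[order][:r], 0.0, None)
    V = evecs[:, order][:, :r]
    V /= np.linalg.norm(V, axis=0, keepdims=True)
    # deterministic sign: largest-|loading| entry positive per axis
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    class_means = table.values.groupby(y).mean().loc[classes]
    return LdaModel(
        directions=V, eigenvalues=evals, class_means=class_means,
        classes=classes, shrinkage=shrinkage,
        scaler_mean=mean, scaler_sd=sd, analytes=table.analytes,
    )


def discrimination_score(
    table: CohortTable,
    folds: int = 5,
    seed: int | None = None,
    shrinkage: float = DEFAULT_SHRINKAGE,
    label: str = "group",
) -> float:
    """Cross-validated nearest-centroid accuracy in discriminant space.

    Stratified k-fold with seeded shuffling; the LDA model is refit on each
    training split.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    y = table.meta[label].to_numpy()
    counts = pd.Series(y).value_counts()
    if (counts < folds).any():
        small = counts[counts < folds].index.tolist()
        raise ValueError(f"group(s) smaller than fold count: {small}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    ids = table.subject_ids
    correct = 0
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        model = fit_lda(table.subset(ids[train_idx]), label=label, shrinkage=shrinkage)
        scores = model.transform(table.values.iloc[test_idx])
        centroids = model.centroids()
        d2 = ((scores[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        pred = np.asarray(model.classes)[np.argmin(d2, axis=1)]
        correct += int((pred == y[test_idx]).sum())
    return correct / len(y)


def scores_frame(model: LdaModel, table: CohortTable) -> pd.DataFrame:
    """Per-subject coordinates on the discriminant axes."""
    coords = model.transform(table.values)
    frame = pd.DataFrame(
        coords, index=table.subject_ids,
        columns=[f"axis_{i + 1}" for i in range(coords.shape[1])],
    )
    frame.insert(0, "group", table.meta["group"].to_numpy())
    return frame
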