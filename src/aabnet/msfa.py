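"""Multi-study factor analysis (MSFA) fit by expectation conditional
maximization (ECM).

Model.  Study ``s`` observes ``n_s`` subjects with p analytes each:

    x_si = mu_s + Lambda f_si + Phi_s l_si + e_si

where ``f ~ N(0, I_K)`` are factor scores common to every study,
``l_s ~ N(0, I_{J_s})`` are study-specific scores, and
``e_si ~ N(0, Psi_s)`` with diagonal ``Psi_s``.  The implied per-study
marginal covariance is

    Sigma_s = Lambda Lambda' + Phi_s Phi_s' + Psi_s.

The common loadings ``Lambda`` capture correlation structure shared across
studies (e.g. healthy donors and a disease cohort); each ``Phi_s`` captures
structure unique to one study.  Maximum likelihood is obtained by ECM: the
E-step computes the conditional moments of the stacked latent vector
``z = (f, l_s)`` given ``x`` (joint-Gaussian conditioning), and three
conditional maximization steps update ``Lambda`` (jointly across studies,
row-wise weighted least squares), each ``Phi_s``, then each ``Psi_s``.  Each
CM step maximizes the expected complete-data log-likelihood in its own block,
so the observed-data log-likelihood is monotone non-decreasing.

Loadings are only identified up to orthogonal rotation; at convergence both
``Lambda`` and each ``Phi_s`` are rotated to lower-triangular form with a
positive diagonal.  Recovery claims should therefore be made on the
rotation-invariant products ``Lambda Lambda'`` and ``Phi_s Phi_s'``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

logger = logging.getLogger(__name__)

PSI_FLOOR_FRACTION = 1e-6  # floor Psi at this fraction of the analyte variance


@dataclass
class MSFAParams:
    """Parameters of the multi-study factor model.

    Attributes
    ----------
    Lambda:
        (p, K) common loading matrix.
    Phi:
        list of (p, J_s) study-specific loading matrices, one per study.
    Psi:
        list of length-p arrays of strictly positive noise variances.
    mu:
        list of length-p study mean vectors.
    analytes:
        optional analyte names (length p).
    """

    Lambda: np.ndarray
    Phi: list[np.ndarray]
    Psi: list[np.ndarray]
    mu: list[np.ndarray]
    analytes: list[str] | None = None

    def __post_init__(self) -> None:
        self.Lambda = np.atleast_2d(np.asarray(self.Lambda, dtype=float))
        if self.Lambda.size == 0:
            self.Lambda = self.Lambda.reshape(self.p_from_psi(), 0)
        self.Phi = [np.asarray(P, dtype=float).reshape(self.Lambda.shape[0], -1) for P in self.Phi]
        self.Psi = [np.asarray(v, dtype=float) for v in self.Psi]
        self.mu = [np.asarray(m, dtype=float) for m in self.mu]
        p = self.Lambda.shape[0]
        for s, (P, v, m) in enumerate(zip(self.Phi, self.Psi, self.mu)):
            if P.shape[0] != p or v.shape != (p,) or m.shape != (p,):
                raise ValueError(f"dimension mismatch in study {s}")
            if np.any(v <= 0):
                raise ValueError(f"Psi must be strictly positive (study {s})")

    def p_from_psi(self) -> int:
        return len(self.Psi[0]) if self.Psi else 0

    @property
    def p(self) -> int:
        return self.Lambda.shape[0]

    @property
    def K(self) -> int:
        return self.Lambda.shape[1]

    @property
    def n_studies(self) -> int:
        return len(self.Psi)

    @property
    def J(self) -> list[int]:
        return [P.shape[1] for P in self.Phi]

    def copy(self) -> "MSFAParams":
        return MSFAParams(
            Lambda=self.Lambda.copy(),
            Phi=[P.copy() for P in self.Phi],
            Psi=[v.copy() for v in self.Psi],
            mu=[m.copy() for m in self.mu],
            analytes=list(self.analytes) if self.analytes else None,
        )


@dataclass
class MSFAFit:
    """Result of an ECM fit: parameters plus the log-likelihood trace."""

    params: MSFAParams
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    tol: float
    seed: int | None = None
    psi_floored: list[list[int]] = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


# ---------------------------------------------------------------------------
# Model quantities
# ---------------------------------------------------------------------------

def marginal_covariance(params: MSFAParams, study: int) -> np.ndarray:
    """Implied marginal covariance Sigma_s = LL' + Phi_s Phi_s' + Psi_s."""
    L, P = params.Lambda, params.Phi[study]
    return L @ L.T + P @ P.T + np.diag(params.Psi[study])


def log_likelihood(data: list[np.ndarray], params: MSFAParams) -> float:
    """Total Gaussian log-likelihood (nats) of per-study data matrices."""
    total = 0.0
    for s, X in enumerate(data):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != params.p:
            raise ValueError(f"study {s}: {X.shape[1]} analytes, expected {params.p}")
        sigma = marginal_covariance(params, s)
        try:
            cho = linalg.cho_factor(sigma, lower=True)
        except linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise ValueError(f"Sigma_{s} is not positive definite") from exc
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        xc = X - params.mu[s]
        quad = np.sum(linalg.cho_solve(cho, xc.T) * xc.T)
        n, p = X.shape
        total += -0.5 * (n * p * np.log(2 * np.pi) + n * logdet + quad)
    return float(total)


# ---------------------------------------------------------------------------
# ECM fitting
# ---------------------------------------------------------------------------

def _standardize_pooled(data: list[np.ndarray]) -> list[np.ndarray]:
    pooled = np.vstack(data)
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return [(X - mean) / sd for X in data]


def _init_pca(data: list[np.ndarray], K: int, J: list[int]) -> MSFAParams:
    """Principal-component initialization from the pooled covariance, with
    per-study residual PCs seeding the specific loadings."""
    p = data[0].shape[1]
    pooled = np.vstack([X - X.mean(axis=0) for X in data])
    S = np.cov(pooled, rowvar=False) if len(pooled) > 1 else np.eye(p)
    S = np.atleast_2d(S)
    w, V = linalg.eigh(S)
    order = np.argsort(w)[::-1]
    w, V = np.clip(w[order], 1e-8, None), V[:, order]
    Lam = V[:, :K] * np.sqrt(w[:K]) if K else np.zeros((p, 0))
    Phi, Psi, mu = [], [], []
    for s, X in enumerate(data):
        mu_s = X.mean(axis=0)
        Xc = X - mu_s
        S_s = np.atleast_2d(np.cov(Xc, rowvar=False)) if len(X) > 1 else np.eye(p)
        R = S_s - Lam @ Lam.T
        if J[s]:
            wr, Vr = linalg.eigh((R + R.T) / 2)
            ordr = np.argsort(wr)[::-1]
            wr = np.clip(wr[ordr][: J[s]], 1e-4, None)
            Phi_s = Vr[:, ordr[: J[s]]] * np.sqrt(wr) * 0.5
        else:
            Phi_s = np.zeros((p, 0))
        resid = np.clip(np.diag(R) - np.sum(Phi_s**2, axis=1), 0.05, None)
        Phi.append(Phi_s)
        Psi.append(resid)
        mu.append(mu_s)
    return MSFAParams(Lambda=Lam, Phi=Phi, Psi=Psi, mu=mu)


def _init_random(data: list[np.ndarray], K: int, J: list[int], rng: np.random.Generator) -> MSFAParams:
    p = data[0].shape[1]
    Lam = rng.normal(scale=0.5, size=(p, K))
    Phi = [rng.normal(scale=0.3, size=(p, J[s])) for s in range(len(data))]
    Psi = [np.full(p, 0.5) for _ in data]
    mu = [X.mean(axis=0) for X in data]
    return MSFAParams(Lambda=Lam, Phi=Phi, Psi=Psi, mu=mu)


def _e_step(Xc: np.ndarray, Lam: np.ndarray, Phi_s: np.ndarray, psi: np.ndarray):
    """Conditional moments of z = (f, l_s) given x for one study.

    Returns (S_xz, S_zz) with S_xz = sum_i xc_i E[z_i]' (p, q) and
    S_zz = sum_i E[z_i z_i'] (q, q)."""
    n = Xc.shape[0]
    Omega = np.hstack([Lam, Phi_s])  # (p, q)
    q = Omega.shape[1]
    if q == 0:
        return np.zeros((Xc.shape[1], 0)), np.zeros((0, 0))
    sigma = Omega @ Omega.T + np.diag(psi)
    cho = linalg.cho_factor(sigma, lower=True)
    M = linalg.cho_solve(cho, Omega)  # Sigma^{-1} Omega, (p, q)
    Ez = Xc @ M  # (n, q)
    V = np.eye(q) - Omega.T @ M  # conditional covariance of z | x
    S_xz = Xc.T @ Ez
    S_zz = n * V + Ez.T @ Ez
    return S_xz, S_zz


def ecm_fit(
    data: list[np.ndarray],
    K: int,
    J: int | list[int],
    *,
    init: str | MSFAParams = "pca",
    tol: float = 1e-6,
    max_iter: int = 2000,
    seed: int | None = None,
    n_starts: int = 5,
    standardize: bool = True,
    psi_floor_fraction: float = PSI_FLOOR_FRACTION,
) -> MSFAFit:
    """Fit the multi-study factor model by maximum likelihood via ECM.

    Parameters
    ----------
    data:
        per-study (n_s, p) matrices over a shared analyte set.
    K, J:
        number of common factors and specific factors (scalar J applies to
        every study).
    init:
        "pca" (deterministic, single start), "random" (``n_starts`` random
        starts, best likelihood kept) or explicit :class:`MSFAParams`.
    standardize:
        z-score each analyte in the pooled sample before fitting (default);
        set False to fit on the raw scale.
    tol:
        relative log-likelihood change below which the fit is converged.
        ``tol=inf`` returns the initialization with a single-point trace.
    """
    data = [np.asarray(X, dtype=float) for X in data]
    if not data:
        raise ValueError("no study data supplied")
    p = data[0].shape[1]
    if any(X.shape[1] != p for X in data):
        raise ValueError("all studies must share the analyte set")
    J = [int(J)] * len(data) if np.isscalar(J) else [int(j) for j in J]
    if len(J) != len(data):
        raise ValueError("J must be scalar or one entry per study")
    if K + max(J, default=0) >= p:
        raise ValueError(f"K + max(J) = {K + max(J, default=0)} must be < p = {p}")
    for s, X in enumerate(data):
        if X.shape[0] <= p:
            logger.warning("study %d has n=%d <= p=%d; estimates may be unstable", s, X.shape[0], p)

    if standardize:
        data = _standardize_pooled(data)

    if isinstance(init, MSFAParams):
        starts: list[MSFAParams] = [init.copy()]
    elif init == "pca":
        starts = [_init_pca(data, K, J)]
    elif init == "random":
        rng = np.random.default_rng(seed)
        starts = [_init_random(data, K, J, rng) for _ in range(n_starts)]
    else:
        raise ValueError(f"unknown init: {init!r}")

    best: MSFAFit | None = None
    for params0 in starts:
        fit = _ecm_single(data, params0, tol=tol, max_iter=max_iter, psi_floor_fraction=psi_floor_fraction)
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    best.seed = seed
    best.params = apply_identifiability(best.params)
    return best


def _ecm_single(
    data: list[np.ndarray],
    params: MSFAParams,
    *,
    tol: float,
    max_iter: int,
    psi_floor_fraction: float,
) -> MSFAFit:
    params = params.copy()
    n_studies = len(data)
    K = params.K
    # Means: exact ML for a Gaussian with free mu_s is the study sample mean.
    params.mu = [X.mean(axis=0) for X in data]
    Xc_list = [X - params.mu[s] for s, X in enumerate(data)]
    n_list = [X.shape[0] for X in data]
    var_list = [np.var(X, axis=0, ddof=0) + 1e-12 for X in data]
    floors = [psi_floor_fraction * v for v in var_list]
    S_xx_diag = [np.sum(Xc**2, axis=0) for Xc in Xc_list]

    trace = [log_likelihood(data, params)]
    floored: list[set[int]] = [set() for _ in range(n_studies)]
    converged = False
    n_iter = 0
    if not np.isfinite(tol):
        return MSFAFit(params=params, loglik_trace=np.asarray(trace), n_iter=0,
                       converged=True, tol=tol)

    for it in range(max_iter):
        # E-step: sufficient statistics per study
        stats = []
        for s in range(n_studies):
            S_xz, S_zz = _e_step(Xc_list[s], params.Lambda, params.Phi[s], params.Psi[s])
            stats.append((S_xz, S_zz))

        # CM-step 1: Lambda, row-wise weighted least squares across studies
        if K:
            new_Lam = np.empty_like(params.Lambda)
            for j in range(params.p):
                A = np.zeros((K, K))
                b = np.zeros(K)
                for s in range(n_studies):
                    S_xz, S_zz = stats[s]
                    S_ff = S_zz[:K, :K]
                    S_lf = S_zz[K:, :K]
                    w = 1.0 / params.Psi[s][j]
                    A += w * S_ff
                    b += w * (S_xz[j, :K] - params.Phi[s][j] @ S_lf)
                new_Lam[j] = linalg.solve(A, b, assume_a="pos")
            params.Lambda = new_Lam

        # CM-step 2: each Phi_s given the new Lambda
        for s in range(n_studies):
            Js = params.Phi[s].shape[1]
            if not Js:
                continue
            S_xz, S_zz = stats[s]
            S_fl = S_zz[:K, K:]
            S_ll = S_zz[K:, K:]
            rhs = S_xz[:, K:] - params.Lambda @ S_fl  # (p, Js)
            params.Phi[s] = linalg.solve(S_ll, rhs.T, assume_a="pos").T

        # CM-step 3: Psi_s given new Lambda, Phi_s
        for s in range(n_studies):
            S_xz, S_zz = stats[s]
            Omega = np.hstack([params.Lambda, params.Phi[s]])
            if Omega.shape[1]:
                cross = np.sum(Omega * S_xz, axis=1)
                quad = np.sum((Omega @ S_zz) * Omega, axis=1)
            else:
                cross = np.zeros(params.p)
                quad = np.zeros(params.p)
            psi = (S_xx_diag[s] - 2 * cross + quad) / n_list[s]
            low = psi < floors[s]
            if low.any():
                floored[s].update(np.flatnonzero(low).tolist())
            params.Psi[s] = np.maximum(psi, floors[s])

        ll = log_likelihood(data, params)
        if not np.isfinite(ll):
            raise FloatingPointError(f"non-finite log-likelihood at iteration {it + 1}")
        trace.append(ll)
        n_iter = it + 1
        rel = abs(ll - trace[-2]) / (abs(trace[-2]) + 1e-12)
        if rel < tol:
            converged = True
            break

    for s, idx in enumerate(floored):
        if idx:
            logger.info("study %d: Psi floored for analytes %s", s, sorted(idx))
    return MSFAFit(
        params=params,
        loglik_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
        tol=tol,
        psi_floored=[sorted(i) for i in floored],
    )


# ---------------------------------------------------------------------------
# Identifiability & dimension choice
# ---------------------------------------------------------------------------

def _lower_triangular_rotation(L: np.ndarray) -> np.ndarray:
    """Rotate loading matrix L (p, k) so its top (k, k) block is lower
    triangular with a positive diagonal.  Rotation-invariant products are
    unchanged."""
    p, k = L.shape
    if k == 0 or p == 0:
        return L.copy()
    # LQ of the top block: L_top = (R Q)' with Q orthogonal
    Q, R = np.linalg.qr(L[:k, :].T)
    rotated = L @ Q
    signs = np.sign(np.diag(rotated[:k, :]))
    signs[signs == 0] = 1.0
    return rotated * signs


def apply_identifiability(params: MSFAParams) -> MSFAParams:
    out = params.copy()
    out.Lambda = _lower_triangular_rotation(out.Lambda)
    out.Phi = [_lower_triangular_rotation(P) for P in out.Phi]
    return out


def n_free_parameters(p: int, K: int, J: list[int], include_means: bool = True) -> int:
    """Free parameters of the model after the triangular identifiability
    constraint: pK - K(K-1)/2 common, p*J_s - J_s(J_s-1)/2 specific per
    study, p noise variances per study, plus p means per study."""
    df = p * K - K * (K - 1) // 2
    for Js in J:
        df += p * Js - Js * (Js - 1) // 2
    df += len(J) * p  # Psi
    if include_means:
        df += len(J) * p
    return df


def choose_dimensions(
    data: list[np.ndarray],
    K_grid: list[int],
    J_grid: list[int],
    *,
    criterion: str = "BIC",
    seed: int | None = None,
    **fit_kwargs,
) -> tuple[int, int, pd.DataFrame]:
    """Grid search over (K, J) by information criterion.

    Returns the argmin (K*, J*) and the full criterion table; grid points
    whose fit fails are recorded with NaN and excluded from the argmin.
    """
    if criterion not in {"BIC", "AIC"}:
        raise ValueError("criterion must be BIC or AIC")
    if not K_grid or not J_grid:
        raise ValueError("grids must be non-empty")
    n_total = sum(X.shape[0] for X in data)
    p = data[0].shape[1]
    rows = []
    for K in K_grid:
        for Jv in J_grid:
            J = [Jv] * len(data)
            try:
                fit = ecm_fit(data, K, J, seed=seed, **fit_kwargs)
                df = n_free_parameters(p, K, J)
                penalty = df * np.log(n_total) if criterion == "BIC" else 2 * df
                score = -2 * fit.loglik + penalty
                rows.append({"K": K, "J": Jv, "loglik": fit.loglik, "df": df,
                             criterion: score, "converged": fit.converged})
            except (ValueError, FloatingPointError) as exc:
                logger.warning("fit failed at K=%d J=%d: %s", K, Jv, exc)
                rows.append({"K": K, "J": Jv, "loglik": np.nan, "df": np.nan,
                             criterion: np.nan, "converged": False})
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=[criterion])
    if valid.empty:
        raise RuntimeError("every grid-point fit failed")
    best = valid.loc[valid[criterion].idxmin()]
    return int(best["K"]), int(best["J"]), table


# ---------------------------------------------------------------------------
# Export / rendering
# ---------------------------------------------------------------------------

def loadings_frame(fit: MSFAFit, study_names: list[str] | None = None) -> pd.DataFrame:
    """Loadings as a tidy frame: analytes x (common factors, then each
    study's specific factors)."""
    params = fit.params
    names = params.analytes or [f"analyte_{i}" for i in range(params.p)]
    studies = study_names or [f"study{s}" for s in range(params.n_studies)]
    blocks = {f"common_{k + 1}": params.Lambda[:, k] for k in range(params.K)}
    for s, P in enumerate(params.Phi):
        for j in range(P.shape[1]):
            blocks[f"{studies[s]}_specific_{j + 1}"] = P[:, j]
    return pd.DataFrame(blocks, index=pd.Index(names, name="analyte"))


def loading_heatmap(fit: MSFAFit, out_prefix: str, study_names: list[str] | None = None):
    """Write the loadings CSV and a heatmap figure with color range [-1, 1]."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = loadings_frame(fit, study_names)
    csv_path = f"{out_prefix}.csv"
    frame.to_csv(csv_path)
    fig, ax = plt.subplots(figsize=(2 + 0.5 * frame.shape[1], 2 + 0.25 * frame.shape[0]))
    im = ax.imshow(frame.to_numpy(), vmin=-1, vmax=1, cmap="PuOr_r", aspect="auto")
    ax.set_xticks(range(frame.shape[1]), frame.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(frame.shape[0]), frame.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="factor loading")
    fig.tight_layout()
    fig_path = f"{out_prefix}.png"
    fig.savefig(fig_path, dpi=150)
    plt.close(fig)
    return csv_path, fig_path
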