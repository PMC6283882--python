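"""Synthetic multi-cohort serology generator.

Cohorts are drawn from the same common/specific latent-factor model the MSFA
estimator fits: per group ``s`` a subject's latent profile is

    x = mu_s + Lambda_s f + Phi_s l + e,      f, l ~ N(0, I),  e ~ N(0, Psi_s)

and is exponentiated by default to give the right-skewed, strictly positive
concentration distributions typical of serology panels.  Rank (Spearman)
statistics are invariant to that monotone transform, so the population
correlation structure implied by the factor model is the network ground
truth for every downstream stage.

Disease-style perturbations operate on one group's parameters only:

``break_pair``
    removes the loading that links a named analyte pair (the second analyte's
    loadings on the factors shared with the first are scaled by ``magnitude``,
    default 0), moving the removed variance into the noise so marginal
    moments of the analyte are preserved in scale.  This reproduces patterns
    such as a disease abolishing the normal AGTR1-EDNRA interconnection.
``scale_spread``
    multiplies the latent scale of named analytes by ``1 + magnitude``
    (magnitude 0 = identity), inflating concentration inequality.
``shift_mean``
    adds ``magnitude`` latent standard deviations to named analytes' means.

An ELISA observation layer maps true concentrations through a five-point
standard curve (2.5-40 U/ml) with response noise and back through the
quantification rule (interpolation on log-concentration between standards,
linear extrapolation beyond), emulating readout error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .msfa import MSFAParams, marginal_covariance

DEFAULT_STANDARDS = (2.5, 5.0, 10.0, 20.0, 40.0)


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerturbationSpec:
    target_group: str
    mode: str  # break_pair | scale_spread | shift_mean
    analytes: tuple[str, ...]
    magnitude: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in {"break_pair", "scale_spread", "shift_mean"}:
            raise ValueError(f"unknown perturbation mode: {self.mode!r}")
        object.__setattr__(self, "analytes", tuple(self.analytes))
        if self.mode == "break_pair" and len(self.analytes) != 2:
            raise ValueError("break_pair needs exactly two analytes")


@dataclass
class GroundTruth:
    """Seed-determined generative model for a set of cohorts.

    Group ``g`` uses common loadings ``Lambda[g]`` (initially identical
    across groups; perturbations make per-group copies diverge), specific
    loadings ``Phi[g]``, noise ``Psi[g]`` and means ``mu[g]``.
    """

    analytes: list[str]
    groups: list[str]
    Lambda: dict[str, np.ndarray]
    Phi: dict[str, np.ndarray]
    Psi: dict[str, np.ndarray]
    mu: dict[str, np.ndarray]
    perturbations: list[PerturbationSpec] = field(default_factory=list)
    transform: str = "exponential"  # or "identity"
    seed: int = 0
    sex_female_fraction: float = 0.7
    age_mean: float = 57.0
    age_sd: float = 13.0
    # mild covariate effects: latent mean shifts applied to the first half of
    # the panel for males / subjects >= 65 (see docs/methods.md)
    sex_shift: float = 0.1
    age_shift: float = 0.2

    def __post_init__(self) -> None:
        if self.transform not in {"identity", "exponential"}:
            raise ValueError(f"unknown transform: {self.transform!r}")

    @property
    def p(self) -> int:
        return len(self.analytes)

    def params_for(self, group: str) -> MSFAParams:
        """Single-study view of one group's parameters."""
        return MSFAParams(
            Lambda=self.Lambda[group],
            Phi=[self.Phi[group]],
            Psi=[self.Psi[group]],
            mu=[self.mu[group]],
            analytes=self.analytes,
        )

    def covariance(self, group: str) -> np.ndarray:
        return marginal_covariance(self.params_for(group), 0)

    def correlation(self, group: str) -> pd.DataFrame:
        """Population (latent-scale Pearson) correlation matrix of a group."""
        sigma = self.covariance(group)
        d = 1.0 / np.sqrt(np.diag(sigma))
        return pd.DataFrame(sigma * np.outer(d, d), index=self.analytes, columns=self.analytes)

    def copy(self) -> "GroundTruth":
        return GroundTruth(
            analytes=list(self.analytes),
            groups=list(self.groups),
            Lambda={g: L.copy() for g, L in self.Lambda.items()},
            Phi={g: P.copy() for g, P in self.Phi.items()},
            Psi={g: v.copy() for g, v in self.Psi.items()},
            mu={g: m.copy() for g, m in self.mu.items()},
            perturbations=list(self.perturbations),
            transform=self.transform,
            seed=self.seed,
            sex_female_fraction=self.sex_female_fraction,
            age_mean=self.age_mean,
            age_sd=self.age_sd,
            sex_shift=self.sex_shift,
            age_shift=self.age_shift,
        )


# ---------------------------------------------------------------------------
# Parameter generation
# ---------------------------------------------------------------------------

def generate_params(
    p: int,
    K: int,
    J: int | list[int],
    n_studies: int,
    *,
    sparsity: float = 0.3,
    seed: int | None = None,
    loading_range: tuple[float, float] = (0.4, 1.0),
    psi_range: tuple[float, float] = (0.2, 0.6),
) -> MSFAParams:
    """Random multi-study factor parameters for recovery experiments.

    Nonzero loadings have magnitude uniform in ``loading_range`` with random
    sign; a ``sparsity`` fraction of entries is exactly 0; noise variances
    are uniform in ``psi_range`` (bounded away from 0).  Fully reproducible
    given ``seed``.
    """
    J = [int(J)] * n_studies if np.isscalar(J) else [int(j) for j in J]
    if len(J) != n_studies:
        raise ValueError("J must be scalar or length n_studies")
    if p < K + max(J, default=0) + 1:
        raise ValueError(f"infeasible dimensions: need p >= K + max(J) + 1, got p={p}")
    rng = np.random.default_rng(seed)

    def _loadings(rows: int, cols: int) -> np.ndarray:
        mag = rng.uniform(*loading_range, size=(rows, cols))
        sign = rng.choice([-1.0, 1.0], size=(rows, cols))
        mask = rng.random((rows, cols)) >= sparsity
        return mag * sign * mask

    Lam = _loadings(p, K)
    Phi = [_loadings(p, J[s]) for s in range(n_studies)]
    Psi = [rng.uniform(*psi_range, size=p) for _ in range(n_studies)]
    mu = [np.zeros(p) for _ in range(n_studies)]
    return MSFAParams(Lambda=Lam, Phi=Phi, Psi=Psi, mu=mu)


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------

def apply_perturbation(truth: GroundTruth, spec: PerturbationSpec) -> GroundTruth:
    """Return a modified copy of the ground truth; other groups untouched."""
    if spec.target_group not in truth.groups:
        raise ValueError(f"unknown group: {spec.target_group!r}")
    idx = []
    for a in spec.analytes:
        if a not in truth.analytes:
            raise ValueError(f"unknown analyte: {a!r}")
        idx.append(truth.analytes.index(a))
    out = truth.copy()
    g = spec.target_group
    L, Psi, mu = out.Lambda[g], out.Psi[g], out.mu[g]
    sigma_diag = np.diag(out.covariance(g))

    if spec.mode == "break_pair":
        a, b = idx
        shared = np.flatnonzero(L[a] != 0)
        removed = L[b, shared] * (1.0 - spec.magnitude)
        # keep the marginal variance of b: move the removed loading variance
        # into the noise term
        old_contrib = np.sum(L[b, shared] ** 2)
        L[b, shared] = L[b, shared] * spec.magnitude
        new_contrib = np.sum(L[b, shared] ** 2)
        Psi[b] += old_contrib - new_contrib
    elif spec.mode == "scale_spread":
        factor = 1.0 + spec.magnitude
        for j in idx:
            L[j] *= factor
            out.Phi[g][j] *= factor
            Psi[j] *= factor**2
    elif spec.mode == "shift_mean":
        for j in idx:
            mu[j] += spec.magnitude * np.sqrt(sigma_diag[j])
    out.perturbations.append(spec)
    return out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(
    truth: GroundTruth,
    group_sizes: dict[str, int],
    *,
    seed: int | None = None,
) -> CohortTable:
    """Draw a cohort table from the ground-truth model.

    Per group the latent draw is x = mu_s + Lambda_s f + Phi_s l + e; sex and
    age are drawn from the truth's demographic settings; mild covariate
    effects shift the latent means of the first half of the panel for males
    and for subjects aged >= 65.  ``seed`` overrides ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    frames_meta, frames_vals = [], []
    half = truth.p // 2
    for group in truth.groups:
        n = int(group_sizes.get(group, 0))
        if n < 0:
            raise ValueError(f"negative group size for {group!r}")
        if n == 0:
            continue
        L, P = truth.Lambda[group], truth.Phi[group]
        f = rng.standard_normal((n, L.shape[1]))
        l = rng.standard_normal((n, P.shape[1]))
        e = rng.standard_normal((n, truth.p)) * np.sqrt(truth.Psi[group])
        x = truth.mu[group] + f @ L.T + l @ P.T + e
        sex = np.where(rng.random(n) < truth.sex_female_fraction, "female", "male")
        age = np.clip(rng.normal(truth.age_mean, truth.age_sd, size=n), 18, 95)
        # mild demographic effects on the latent scale
        x[:, :half] += truth.sex_shift * (sex == "male")[:, None]
        x[:, :half] += truth.age_shift * (age >= 65)[:, None]
        if truth.transform == "exponential":
            x = np.exp(x)
        else:
            # identity transform keeps the Gaussian scale; shift each analyte
            # to nonnegative concentrations (correlations and covariances are
            # unchanged by a per-analyte constant shift)
            col_min = x.min(axis=0)
            x = x - np.minimum(col_min, 0.0)
        ids = [f"{group}_{i:04d}" for i in range(n)]
        frames_meta.append(
            pd.DataFrame({"group": group, "sex": sex, "age": np.round(age, 1)},
                         index=pd.Index(ids, name="subject_id"))
        )
        frames_vals.append(
            pd.DataFrame(x, index=pd.Index(ids, name="subject_id"), columns=truth.analytes)
        )
    if not frames_meta:
        raise ValueError("all group sizes are zero")
    return CohortTable(pd.concat(frames_meta), pd.concat(frames_vals))


# ---------------------------------------------------------------------------
# ELISA standard-curve observation layer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardCurve:
    """Five-point ELISA standard curve (concentration, response) pairs.

    The default is log-linear through standards at 2.5-40 U/ml; responses
    must be strictly increasing with concentration.
    """

    concentrations: tuple[float, ...] = DEFAULT_STANDARDS
    responses: tuple[float, ...] | None = None
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if np.any(np.diff(conc) <= 0) or np.any(conc <= 0):
            raise ValueError("standard concentrations must be positive and increasing")
        if self.responses is None:
            # log-linear response: 0.05 OD at the lowest standard, +0.5 per
            # doubling of concentration
            resp = 0.05 + 0.5 * np.log2(conc / conc[0])
            object.__setattr__(self, "responses", tuple(resp))
        resp = np.asarray(self.responses, dtype=float)
        if resp.shape != conc.shape:
            raise ValueError("responses must match standards")
        if np.any(np.diff(resp) <= 0):
            raise ValueError("responses must be strictly increasing")

    @property
    def log_conc(self) -> np.ndarray:
        return np.log(np.asarray(self.concentrations, dtype=float))

    def forward(self, conc: np.ndarray) -> np.ndarray:
        """Map concentration to expected response (piecewise linear in log
        concentration, linearly extrapolated beyond the standards)."""
        logc = np.log(np.clip(np.asarray(conc, dtype=float), 1e-12, None))
        return _interp_extrap(logc, self.log_conc, np.asarray(self.responses))

    def invert(self, response: np.ndarray) -> np.ndarray:
        """Quantification rule: response -> concentration via interpolation
        on log-concentration, linear extrapolation beyond the curve."""
        logc = _interp_extrap(np.asarray(response, dtype=float),
                              np.asarray(self.responses), self.log_conc)
        return np.exp(logc)


def _interp_extrap(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """np.interp with linear extrapolation beyond the knots."""
    y = np.interp(x, xp, fp)
    lo = x < xp[0]
    hi = x > xp[-1]
    if lo.any():
        slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        y = np.where(lo, fp[0] + slope * (x - xp[0]), y)
    if hi.any():
        slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y = np.where(hi, fp[-1] + slope * (x - xp[-1]), y)
    return y


def elisa_observe(
    true_conc: np.ndarray | pd.DataFrame,
    curve: StandardCurve,
    seed: int | None = None,
) -> tuple[np.ndarray | pd.DataFrame, np.ndarray]:
    """Simulate ELISA readout: forward-map concentrations to responses, add
    response noise, and invert via the quantification rule.

    Returns (observed concentrations clamped >= 0, below-range flags) where
    a flag marks a noisy response below the lowest standard's response.
    """
    is_frame = isinstance(true_conc, pd.DataFrame)
    arr = true_conc.to_numpy(dtype=float) if is_frame else np.asarray(true_conc, dtype=float)
    rng = np.random.default_rng(seed)
    resp = curve.forward(arr)
    if curve.noise_sd > 0:
        resp = resp + rng.normal(scale=curve.noise_sd, size=resp.shape)
    below = resp < np.asarray(curve.responses)[0]
    observed = np.maximum(curve.invert(resp), 0.0)
    if is_frame:
        observed = pd.DataFrame(observed, index=true_conc.index, columns=true_conc.columns)
    return observed, below


# ---------------------------------------------------------------------------
# Bundled study scenario
# ---------------------------------------------------------------------------

#: Receptor-family factor blocks of the bundled panel.
PANEL_FAMILIES: dict[str, tuple[str, ...]] = {
    "vascular": ("AGTR1", "EDNRA"),
    "muscarinic": ("CHRM1", "CHRM2", "CHRM3", "CHRM4"),
    "protease": ("F2R", "F2RL1"),
    "chemokine": ("CXCR3", "CXCR4"),
    "adrenergic": ("ADRB1", "ADRB2"),
    "growth": ("EGFR", "FLT1", "KDR", "PDGFRB"),
}

#: Default cohort sizes mirroring the study's serology cohorts.
DEFAULT_GROUP_SIZES: dict[str, int] = {"HD": 196, "SSc": 84, "OC": 207, "AD": 91}


def default_scenario(seed: int = 0, *, transform: str = "exponential") -> GroundTruth:
    """The bundled healthy-donor vs disease scenario.

    A 16-analyte panel organised in six receptor-family factor blocks
    (within-block population correlation ~0.78, between-block 0), four
    groups (HD, SSc, OC, AD) and perturbations graded by disease severity:

    - SSc (strong): breaks the F2R-F2RL1 pair, inflates the spread of the
      vascular analytes, and shifts six analytes by 0.8-1.5 latent SD.
    - OC (mild): +0.4 SD shifts on three analytes.
    - AD (mild): +0.35 SD shifts on three analytes and one broken
      muscarinic pairing at reduced magnitude.
    """
    analytes = [a for fam in PANEL_FAMILIES.values() for a in fam]
    groups = ["HD", "SSc", "OC", "AD"]
    p, K = len(analytes), len(PANEL_FAMILIES)
    lam = 0.88  # with psi = 1 - lam^2: within-block correlation ~0.775
    Lam = np.zeros((p, K))
    for k, fam in enumerate(PANEL_FAMILIES.values()):
        for a in fam:
            Lam[analytes.index(a), k] = lam
    psi = np.full(p, 1.0 - lam**2)
    truth = GroundTruth(
        analytes=analytes,
        groups=groups,
        Lambda={g: Lam.copy() for g in groups},
        Phi={g: np.zeros((p, 0)) for g in groups},
        Psi={g: psi.copy() for g in groups},
        mu={g: np.zeros(p) for g in groups},
        transform=transform,
        seed=seed,
    )
    perturbations = [
        # SSc-like: strong, multi-modal disruption
        PerturbationSpec("SSc", "break_pair", ("F2R", "F2RL1"), 0.0),
        PerturbationSpec("SSc", "scale_spread", ("AGTR1", "EDNRA"), 1.0),
        PerturbationSpec("SSc", "shift_mean", ("AGTR1",), 1.5),
        PerturbationSpec("SSc", "shift_mean", ("CHRM3",), 1.2),
        PerturbationSpec("SSc", "shift_mean", ("F2R",), 1.2),
        PerturbationSpec("SSc", "shift_mean", ("CXCR3",), -1.0),
        PerturbationSpec("SSc", "shift_mean", ("EGFR",), 1.2),
        PerturbationSpec("SSc", "shift_mean", ("KDR",), -0.8),
        # OC-like: mild shifts
        PerturbationSpec("OC", "shift_mean", ("EGFR",), 0.4),
        PerturbationSpec("OC", "shift_mean", ("CXCR4",), 0.4),
        PerturbationSpec("OC", "shift_mean", ("FLT1",), -0.35),
        # AD-like: mild shifts plus a weakened muscarinic pairing
        PerturbationSpec("AD", "shift_mean", ("CHRM1",), 0.35),
        PerturbationSpec("AD", "shift_mean", ("ADRB2",), 0.35),
        PerturbationSpec("AD", "shift_mean", ("CHRM4",), -0.3),
        PerturbationSpec("AD", "break_pair", ("CHRM1", "CHRM2"), 0.5),
    ]
    for spec in perturbations:
        truth = apply_perturbation(truth, spec)
    return truth
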