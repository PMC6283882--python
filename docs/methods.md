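# Methods

`aabnet` analyses panels of autoantibody (aab) concentrations measured by
sandwich ELISA in arbitrary units (U/ml) across multiple cohorts — healthy
donors (HD) and disease groups such as systemic sclerosis (SSc), ovarian
cancer (OC), and Alzheimer's disease (AD).  The scientific object of
interest is not the individual concentration but the *correlation
signature*: which aab rise and fall together, how that network is organised
into modules of structurally/functionally related receptor targets, and how
demographics and disease perturb it.  This note records the models, the
defaults, and the design decisions behind each stage.

## Synthetic cohort model

No patient-level data ship with the package; every analysis is exercised on
synthetic cohorts drawn from the same latent-factor model the estimator in
`aabnet.msfa` fits.  A subject in group *s* has a latent profile

    x = mu_s + Lambda_s f + Phi_s l + e,   f ~ N(0, I_K), l ~ N(0, I_{J_s}),
    e ~ N(0, Psi_s),  Psi_s diagonal,

so the group's population covariance is `Sigma_s = Lambda_s Lambda_s' +
Phi_s Phi_s' + Psi_s`.  By default the latent profile is exponentiated,
giving the right-skewed, strictly positive concentration distributions
typical of serology.  Because Spearman statistics are invariant under
strictly monotone transforms, the factor model's correlation structure is
the exact ground truth for the rank-based network stages even after
exponentiation.  An identity transform is retained for covariance-level
recovery experiments; there each analyte is shifted by a constant to keep
concentrations nonnegative, which leaves correlations and covariances
untouched.

The bundled scenario uses a 16-analyte panel organised in six
receptor-family factor blocks (vascular AGTR1/EDNRA, muscarinic CHRM1-4,
protease-activated F2R/F2RL1, chemokine CXCR3/CXCR4, adrenergic ADRB1/2,
and growth-factor receptors EGFR/FLT1/KDR/PDGFRB).  The block loading is
0.88 on unit-variance analytes, i.e. within-block population correlation
~0.775 — comfortably above the 0.6 network threshold — and zero between
blocks.  Group sizes default to HD 196, SSc 84, OC 207, AD 91, mirroring
the serology cohorts the analyses are modeled on.  Demographics default to
70% female, age ~ N(57, 13) clipped to [18, 95]; mild covariate effects
(latent mean shifts of 0.1 for males and 0.2 for subjects >= 65, applied to
the first half of the panel) make sex/age-stratified analyses differ
detectably but mildly.  The real panels' distributional summaries are not
published, so these are scenario parameters, not estimates.

Disease perturbations are graded by severity:

- **SSc-like (strong)** — breaks the F2R-F2RL1 pair, doubles the latent
  spread of AGTR1/EDNRA, and shifts six analytes by 0.8-1.5 latent SD with
  mixed signs.
- **OC-like / AD-like (mild)** — 0.3-0.4 SD shifts on three analytes each;
  the AD-like group additionally halves the muscarinic loading of CHRM2.

`break_pair` rescales the second analyte's loadings on the factors it
shares with the first (default factor 0, a full break) and moves the
removed loading variance into the noise term, so the analyte's marginal
variance is preserved and only the named correlation structure changes.
`scale_spread` multiplies the latent scale by `1 + magnitude` (magnitude 0
is the identity).  `shift_mean` moves the group mean in units of the
analyte's latent SD.  Perturbations are local: analytes not named keep
their population moments.

The ELISA observation layer maps true concentrations through a five-point
standard curve spanning 2.5-40 U/ml (log-linear by default: response
0.05 + 0.5 per doubling), adds Gaussian response noise, and inverts via the
quantification rule — interpolation on log concentration between standards,
linear extrapolation beyond, with readings below the lowest standard's
response flagged "below range".  A log-linear curve was chosen over 4PL
because it is exactly invertible without iteration; the curve's knots and
responses are configurable.  Optical plate effects and antibody
affinity/avidity are deliberately out of scope.

What passing tests on these cohorts do *not* show: robustness to assay
batch effects, censoring at the quantification limits, non-Gaussian latent
dependence (e.g. tail dependence), or outlying subjects — none of which the
generator emulates.

## Group comparisons

Per-analyte two-group tests use the Mann-Whitney U (midranks for ties).
The reported U counts (x, y) pairs in which x precedes y, ties 1/2, so
U(x,y) + U(y,x) = n1*n2 exactly.  Exact p-values are computed when both
samples have n <= 8 without ties; otherwise a tie-corrected normal
approximation with continuity correction.  Panels report raw *and*
Benjamini-Hochberg adjusted p-values: source analyses of this kind
typically report raw p <= 0.05 across >= 10 analytes, so multiplicity is
surfaced rather than silent.  A direction (increased/decreased) is declared
only when the adjusted p clears alpha; otherwise "unchanged" regardless of
the median difference sign.

## Correlation networks

Correlation matrices are pairwise-complete with a per-cell minimum sample
size (default `min_n = 10`; cells below it are set missing).  Networks keep
an edge when the correlation strictly exceeds the threshold.  The default
rule is *signed* rho > 0.6 — matching the convention that circle plots draw
only correlations above 0.6 and that the plotted networks are positive
association networks — with an absolute-value rule available by flag.  Edge
weights keep the raw rho for line-width rendering; no p-value filter is
applied to edges.  Network comparison is purely set-based: Jaccard overlap
plus lost/gained edge lists, with Jaccard defined as 1 when both edge sets
are empty.

## Gini inequality

The Gini coefficient is the mean absolute difference over all ordered pairs
divided by twice the mean, computed by the O(n log n) sorted identity
`g = 2 sum(i * x_(i)) / (n * sum(x)) - (n+1)/n`.  The uncorrected
(population) estimator matches the all-pairs definition verbatim; the
small-sample n/(n-1) factor is a flag.  Confidence intervals are seeded
equal-tailed percentile bootstrap, default B = 1000 at 95% (the bootstrap
variant and replicate count are explicit choices; BCa is deliberately not
used).  Known limitation: for heavy-tailed concentration distributions the
percentile bootstrap undercovers somewhat (≈88-90% observed coverage at
nominal 95% for lognormal data at n = 200), because the plug-in Gini is
biased downward on resamples; the test suite documents this behaviour
rather than hiding it.  Zeros are legal concentrations; missing values are
dropped per analyte.

## Signature clustering

The signature matrix stacks, per stratum, each analyte's within-stratum
correlation profile: rows are (stratum, analyte) pairs, columns analytes.
Within-stratum correlations default to Pearson for this stage (the
rank-based matrices remain available), rows are compared with distance
1 - Pearson correlation between profiles — invariant to adding a constant
to a row — and merged by average linkage.  Columns are clustered the same
way on the transpose.  Ties in the agglomeration follow the deterministic
lowest-index convention of the underlying linkage routine, so trees are
stable across runs.  Missing correlation cells (from the pairwise `min_n`
rule) raise by default; with imputation enabled they are mean-imputed per
column and rows with more than 20% missing are dropped, with counts logged.
Cluster quality against planted or external labels is scored by the
adjusted Rand index.  Heatmap color ranges default to (-0.6, 0.9) for
signature correlograms and (0, 1) for plain correlation heatmaps.

## Linear discriminant analysis

Fisher LDA on z-scored analytes, with the within-class scatter shrunk
toward its diagonal, `(1-s) S_W + s diag(S_W)`, default s = 0.1 — serology
panels can have width comparable to group size, and the diagonal shrinkage
keeps the generalized eigenproblem well posed.  At s = 0 (and without
standardization) the eigenvalues are affine-equivariant, as Fisher LDA
should be.  Axes are unit vectors with a deterministic sign (largest
loading positive), at most min(p, g-1) of them.  Separation is summarized
by stratified k-fold nearest-centroid accuracy in discriminant space with
seeded fold assignment; the model is refit on each training split.

## Multi-study factor analysis (MSFA)

The estimator for the common/specific factor model is maximum likelihood
via expectation conditional maximization.  The E-step computes the
conditional moments of the stacked latent vector z = (f, l_s) given x by
joint-Gaussian conditioning on `Sigma_s`.  Three CM steps then update, in
order: the common loadings Lambda — jointly across studies, row-wise
weighted least squares with weights 1/psi_sj — then each study's Phi_s,
then each Psi_s.  Each step maximizes the expected complete-data
log-likelihood in its own block, so the observed log-likelihood is monotone
non-decreasing; the test suite asserts no decrease beyond 1e-8 per
iteration.  Study means are the exact Gaussian ML (study sample means).

Numerical choices:

- **Preprocessing** — per-analyte z-scoring in the pooled sample by default
  (raw-scale fitting by flag); the cohort pipelines fit on log
  concentrations because the default generator is log-normal.
- **Heywood guard** — Psi is floored at 1e-6 of each analyte's variance;
  floored analytes are recorded on the fit object.
- **Initialization** — "pca" (deterministic): pooled-covariance principal
  components for Lambda, per-study residual PCs for Phi_s, residual
  variances for Psi_s; "random" runs 5 seeded starts and keeps the best
  likelihood.
- **Convergence** — relative log-likelihood change < 1e-6, max 2000
  iterations; `tol=inf` returns the initialization with a one-point trace
  (useful as a degenerate control).
- **Identifiability** — loadings are only identified up to orthogonal
  rotation, so at convergence Lambda and each Phi_s are rotated to
  lower-triangular form with positive diagonal (post hoc, keeping the CM
  steps unconstrained).  Recovery claims are always made on the invariant
  products `Lambda Lambda'` and `Phi_s Phi_s'`, never on raw loadings.

Dimensions (K, J) are chosen by BIC (or AIC) over a user grid; the free
parameter count subtracts the K(K-1)/2 and J_s(J_s-1)/2 rotational degrees
of freedom removed by the triangular constraint.  The criterion table is
returned in full so the choice is transparent.  With a single study and
J = 0 the model reduces to classical factor analysis; the fitted marginal
covariance agrees with an independent EM factor-analysis implementation to
< 1e-6 Frobenius on standardized data in the validation suite.

## Problem sizes used in validation

The validation experiments run at the scale the analyses are designed for:
network recovery uses 100 replicates of n = 1000 subjects on a 10-analyte
2-block panel; clustering recovery n = 500; ECM monotonicity 50 random fits
of 3 studies x 100 subjects x 10 analytes; MSFA recovery 3 studies x 500
subjects x 15 analytes; bootstrap coverage 500 Monte-Carlo replicates of
n = 200 with B = 1000; LDA ordering uses the bundled cohort sizes
(196/84/207/91).  These sizes are the package's own study conditions and
are fixed in the test suite and acceptance script.

## Known limitations

- Networks are marginal-correlation graphs; no partial-correlation or
  graphical-model inference, so hub structure can reflect shared factors
  rather than direct coupling.
- The percentile-bootstrap Gini CI undercovers on heavy-tailed data (see
  above).
- MSFA likelihoods are multimodal; the deterministic PCA start is
  reproducible but not guaranteed global — use random multi-start for
  confirmation on real data.
- The generator's analyte registry maps receptor abbreviations to display
  labels only; no biology is inferred from names.
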