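# Methods

`longsad` implements structured-antedependence (SAD) mixed models for
longitudinal residual feed intake (RFI) in growing animals, together with the
machinery those models need: pedigree relationship matrices, REML estimation,
BLUP of time-specific breeding values, and eigen-based selection criteria.
This note records the model, the numerical choices, what the synthetic-data
generator does and does not emulate, and known limitations.

## The model

Four traits are observed weekly on each animal over a test period of `n`
weeks: average daily gain (ADG, 10 g/d), metabolic body weight
(MBW = BW^0.6, 10 x kg^0.6), backfat thickness (BF, 0.1 mm) and feed intake
(FI, 10 g/d).  Each trait decomposes into fixed effects, an additive genetic
effect and a residual, and both random parts follow first-order
antedependence in time:

    u_{s,j} = theta_{s,j} u_{s,j-1} + eps_{s,j},   var(eps_{s,j}) = sigma2_{s,j},

with theta(t) a polynomial of time and log sigma2(t) another (the exp link
keeps every innovation variance positive; heritabilities are automatically in
[0,1]).  The first time point has no antedependence term.  FI additionally
regresses on the *contemporaneous* random effects of the production traits —
cross-antedependence — with polynomial coefficients b_u(t) (genetic part) and
b_e(t) (residual part).  Production traits are mutually independent;
covariances among them and FI arise only through the FI rows.

Stacking trait-by-time cells gives `Sigma^{-1} = L' D^{-1} L` with L unit
lower triangular (negated antedependence and cross-antedependence entries)
and D the innovation variances; all covariance matrices in the package are
built from this factorisation by triangular solves, never explicit inverses.

Two RFI criteria are derived:

* **Phenotypic regression model** — a single-response SAD model of FI with
  week-nested fixed regressions on the observed production phenotypes; RFI is
  the genetic-plus-residual effect of that model.
* **Multi-SAD regression model** — the joint four-trait fit; RFI* adjusts FI
  at both levels using the *genetic* coefficients:

      u*_j = u_FI,j + theta_uFI,j (u*_{j-1} - u_FI,j-1) - sum_s b_{u,s,j} u_{s,j}

  and analogously for e* (with b_u, following the defining equations; a
  variant using b_e — independent at the phenotypic level as well — is
  available via `coefficients="environmental"` but is never the default).
  G* of RFI* is the plain SAD covariance built from FI's genetic theta and
  innovation variances; P* = B P_T B', where the FI row blocks of B unroll
  the e* recursion: entry (j, m), m <= j, equals
  `-(prod_{k=m+1..j} theta_eFI,k) * b_{u,s,m}`.  By construction the genetic
  covariance between RFI* and every production trait is zero at every week
  pair; the package verifies this against direct simulation of the
  recursions.

A caution on reading coefficients off covariances: the marginal ratio
`cov(u_s,j, u_FI,j)/var(u_s,j)` equals b_{u,s}(t_j) only at the first week —
for later weeks the lagged FI term also covaries with u_s,j.  The exact
identity at every week is the partial regression of u_FI,j on the
contemporaneous production effects and u_FI,j-1 (the recursion's own
projection); `regression_trajectories` reports that quantity as
`b_u_implied` alongside the fitted polynomials.

## Estimation

REML on the observed records, `y ~ N(X beta, Z (A ox Sigma_g) Z' + I ox
Sigma_e)`, with `A` the numerator relationship matrix (tabular method, exact
inbreeding; Henderson-rule sparse inverse available).  Two numerically
identical likelihood backends:

* **eigen** (complete balanced records): with `A = U diag(lambda) U'`,
  rotating the animal axis block-diagonalises V into per-animal
  `lambda_i Sigma_g + Sigma_e` blocks; the criterion is accumulated with
  batched Cholesky factorisations.  Cost is linear in animals.
* **dense** (arbitrary missingness): V restricted to observed cells,
  built explicitly.  Missing cells are dropped from the likelihood — never
  imputed; interpolation is an explicit preprocessing step.

The REML value includes the `-log|X'X|` constant so it equals the
null-space-projection form exactly; the test suite holds the two backends and
an independently coded projection oracle to 1e-8 of each other.

Maximisation is quasi-Newton (L-BFGS-B) with numerical gradients on the raw
coefficient vector.  Because a degree-q coefficient's effect scales like
t^q, the optimiser works on z_q = c_q * s^q with s half the time range; this
preconditioning cuts iteration counts several-fold and changes nothing else.
Convergence: relative criterion change below 1e-10 (L-BFGS-B ftol); jittered
restarts if no finite optimum is found.  Standard errors come from a central
finite-difference Hessian of the restricted likelihood at the optimum
(the information matrix), computed in the original coefficient space.

The **two-stage scheme** first fits each production trait with its
single-trait SAD model, then freezes those parameters in the joint fit
(`two_stage=True`, the default) — the same convergence device used in the
study the package emulates.  Cross coefficients are started from week-wise
phenotypic regressions of FI on each production trait.

**Degree selection** (`select_degrees`) is best-first forward stepwise: per
trait, every live move (raise the antedependence or log-variance degree, in
either component) is evaluated each round and the *most significant*
improvement is kept, judged by the REML likelihood ratio test at
alpha = 0.05 (naive chi-square; a 50:50 boundary mixture is available).
Accepting the first significant move in a fixed order instead would let a
genetic term absorb an unmodelled environmental variance trend merely
because it is tested first.  A move that tests non-significant is capped —
not retried after later acceptances — matching "no further significant
improvement" while avoiding repeated 5% gambles on the same direction.
Candidate models are warm-started by embedding the incumbent's coefficients
(new higher-degree terms at zero), so a candidate starts exactly at the
incumbent's likelihood and a poorly converged from-scratch refit can never
masquerade as evidence for the extra term.  Cross-antedependence degrees are
then raised jointly across targets and components.  The exact alpha used in
the original study is not stated; 0.05 is the package default.

BLUP: `u_hat = (A[:, phi] ox Sigma_g) Z' V^{-1} (y - X beta_hat)` gives every
pedigree animal a trait-by-week trajectory; residual BLUPs supply the e
components of RFI at unobserved cells (their conditional expectations).
`information_condition_number` reports sqrt(lambda_max/lambda_min) of the
information matrix and flags values above 1000 as a practical
identifiability concern.

## Selection outputs

Eigendecomposition of the genetic covariance of RFI (G or G*) defines
summarised breeding values: SBV_k = TEBV . v_k.  Eigenvector signs are fixed
by non-negative entry sums so SBV are reproducible across platforms; this
matters because the interpretation of SBV2 (early-vs-late contrast) depends
on sign.  Trajectory clustering is k-means (k = 3 by default, 25 restarts,
fixed seed), with clusters relabelled by ascending mean so labels are
deterministic.  Cohen's kappa between two clusterings is computed after
optimal (Hungarian) label matching, since raw k-means labels are arbitrary.
Weekly EBV agreement uses Spearman correlations with Fisher-z intervals.

## The synthetic world

The study's pig dataset is not public, so the generator is the test bed.
Defaults emulate the published description: 10 weekly measurements, weekly
trait means and missingness rates set to the published descriptive table,
the retained SAD structures (ADG SAD00/SAD00, MBW SAD00/SAD01, BF
SAD00/SAD01, FI SAD11/SAD12, degree-1 cross functions in both components),
and cross-coefficient trajectories with the published week-1 values and
slopes (e.g. genetic ADG coefficient 1.13 at week 1, slope -0.06; MBW 1.48,
slope -0.17; BF constant 0.18).

The within-trait theta and innovation-variance values are *not* published.
They are calibrated once so that the implied phenotypic SDs track the
published weekly SDs and the implied heritabilities track the published
trajectories (FI 0.20 to 0.39, ADG 0.32 to 0.39, MBW 0.21 to 0.60, BF 0.27
to 0.48); the FI log-variance coefficients were solved numerically under
the full multi-trait construction and frozen.  The published genetic
variance *ranges* for MBW (5 to 66) cannot be reproduced exactly by any
SAD00 structure (a 10-step order-1 chain with constant innovation variance
caps the variance rise at 10x and pins week 1 to the innovation variance),
so the SD/heritability calibration takes precedence.  Under these defaults
RFI* heritability comes out 0.13-0.32 across weeks — the same moderate range
the study reports, though not matched point-for-point.

Pedigrees are discrete generations with random mating; genetic effects are
drawn through Cholesky factors of A and of the joint SAD covariance (or,
equivalently, by iterating the defining recursions on A-correlated
innovations — both exposed, and their agreement is itself a test).
Missingness is completely at random at per-trait, per-week rates; the real
study's missingness is design-driven (sex-specific weighing schedules), so
per-animal record counts differ: under MCAR some animals have fewer than two
records of a trait and cannot be interpolated, which the real design
precluded.  Fixed effects default to week means only; batch/sex/pen exist in
the study but add nothing to the properties tested here.  Latent body-weight
tracks for exercising the ADG/MBW derivation use a plain growth series —
there is no published BW-level generative model.

A green test on this world establishes that the estimation machinery
recovers the parameters of a correctly specified SAD world at desk scale;
it does not establish anything about feeder behaviour, diet, or the real
selection lines.

## Known limitations and honest disagreements

* Antedependence order is fixed at 1; higher orders are out of scope.
* Dense algebra limits the package to a few thousand animals; the eigen
  backend needs complete balanced records, the dense backend is quadratic in
  observed cells.
* In a fully longitudinal world the phenotypic-regression model is
  structurally misspecified: its stacked residual correlates with *lagged*
  production covariates (through theta_FI x b terms), so its week-slopes are
  attenuated and its RFI diverges from RFI* increasingly over weeks even
  when the Kennedy proportionality condition holds at every week.  The
  acceptance test of that idealised equivalence documents the observed
  disagreement rather than hiding it; see the test docstrings.
* Exact re-selection of the generating polynomial degrees by stepwise LRT is
  a low-probability event at desk-scale n: each of ~16 true-null moves has a
  ~5% false-acceptance chance and the low-magnitude slopes (e.g. the FI
  environmental antedependence slope) have modest single-trait power, so the
  re-selection acceptance test is expected to be sensitive to sample size.
* The published outlier-removal rule is delegated to a citation and not
  reproduced; an optional |z| > 4 within trait-week filter is provided as a
  clearly labelled stand-in.
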