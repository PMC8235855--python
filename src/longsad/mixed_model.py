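"""REML estimation of SAD animal models, BLUP, and model selection.

Model: stacked records y (animal x trait x week, observed cells only),

    y = X beta + Z u + e,   u ~ N(0, A (x) Sigma_g),   e ~ N(0, I (x) Sigma_e),

with ``A`` the numerator relationship matrix and Sigma_g, Sigma_e the joint
trait-by-time SAD covariances.  The restricted likelihood is maximised by
quasi-Newton iteration on the unconstrained polynomial coefficient vector
(log-link innovation variances keep every variance positive).

Two numerically identical likelihood backends are used:

* ``eigen`` — for complete, balanced records.  With A = U diag(lambda) U',
  rotating the animal axis by U' block-diagonalises V into per-animal blocks
  lambda_i Sigma_g + Sigma_e; the REML criterion is accumulated over blocks.
* ``dense`` — for arbitrary missingness, building V on the observed cells
  directly.  Desk-scale only; it is the reference the fast path must match.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .pedigree import RelationshipMatrix
from .phenotypes import PhenotypeTable
from .sad import (
    COMPONENTS,
    ENVIRONMENTAL,
    GENETIC,
    SadParams,
    SadSpec,
    TimeGrid,
    multi_trait_covariance,
)

__all__ = [
    "FixedSpec",
    "DesignError",
    "MixedModelData",
    "build_design",
    "params_to_vector",
    "vector_to_params",
    "parameter_names",
    "production_freeze_mask",
    "restricted_loglik",
    "FitResult",
    "fit_reml",
    "lrt",
    "SearchPlan",
    "select_degrees",
    "blup_solve",
    "information_condition_number",
]

_BAD = -1.0e30  # sentinel for a non-finite restricted log-likelihood


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class FixedSpec:
    """Fixed-effect description, applied per trait.

    Every trait always gets its own week-specific intercepts.  ``factors``
    are categorical columns of the phenotype table (treatment contrasts,
    first level as reference, effects shared across weeks within a trait);
    ``covariates`` are numeric columns with a single slope per trait;
    ``week_trait_covariates`` maps a response trait to other traits whose
    *values* enter its mean with a separate slope per week — the phenotypic
    regression coefficients b_sj of the phenotypic-regression RFI model.
    """

    factors: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()
    week_trait_covariates: dict = field(default_factory=dict)


@dataclass
class MixedModelData:
    """Wide arrays ready for the likelihood."""

    animals: list[str]
    traits: tuple[str, ...]
    grid: TimeGrid
    Y: np.ndarray            # (N, m) with NaN at unobserved cells
    X: np.ndarray            # (N, m, p)
    columns: list[tuple]
    A_sub: np.ndarray        # (N, N) relationship among phenotyped animals

    def __post_init__(self):
        self.mask = ~np.isnan(self.Y)
        self.complete = bool(self.mask.all())
        self._eig = None
        self._cache = {}

    @property
    def n_obs(self) -> int:
        return int(self.mask.sum())

    @property
    def p(self) -> int:
        return self.X.shape[2]

    def eig(self):
        if self._eig is None:
            lam, U = np.linalg.eigh(self.A_sub)
            Yt = U.T @ np.nan_to_num(self.Y)
            Xt = np.einsum("ab,bmp->amp", U.T, self.X)
            XtX = np.einsum("amp,amq->pq", self.X, self.X)
            self._eig = (lam, U, Yt, Xt, XtX)
        return self._eig


def build_design(
    pheno: PhenotypeTable,
    fixed: FixedSpec,
    grid: TimeGrid,
    traits: tuple[str, ...],
    A: RelationshipMatrix | np.ndarray,
    animals: list[str] | None = None,
) -> MixedModelData:
    """Assemble wide response/design arrays and the A submatrix.

    Raises :class:`DesignError` if a referenced column is absent, if a
    week-nested trait covariate is missing where its response is observed,
    or if the fixed part is rank deficient after treatment constraints.
    """
    animals, Y, mask = pheno.to_wide(list(traits), grid, animals)
    n, T = grid.n, len(traits)
    df = pheno.data
    for col in tuple(fixed.factors) + tuple(fixed.covariates):
        if col not in df.columns:
            raise DesignError(f"unknown fixed-effect column {col!r}")

    # per-record lookup of extra columns, keyed by (animal, week, trait)
    extra = list(fixed.factors) + list(fixed.covariates)
    rec = df.set_index(["animal", "week", "trait"]) if extra else None

    columns: list[tuple] = []
    for s in traits:
        columns += [(s, "week", int(t)) for t in grid.times]
        for f in fixed.factors:
            levels = sorted(df[f].astype(str).unique())
            columns += [(s, f, lev) for lev in levels[1:]]
        columns += [(s, "cov", c) for c in fixed.covariates]
        for src in fixed.week_trait_covariates.get(s, ()):
            columns += [(s, f"b_{src}", int(t)) for t in grid.times]
    p = len(columns)
    cpos = {c: k for k, c in enumerate(columns)}

    apos = {a: i for i, a in enumerate(animals)}
    X = np.zeros((len(animals), T * n, p))
    weeks = [int(t) for t in grid.times]

    # trait-week intercepts
    for si, s in enumerate(traits):
        for j, w in enumerate(weeks):
            X[:, si * n + j, cpos[(s, "week", w)]] = 1.0

    # factor contrasts / covariates from the record's own row
    if extra:
        sub = df[df["trait"].isin(traits) & df["week"].isin(weeks)]
        for row in sub.itertuples(index=False):
            a, w, s = str(row.animal), int(row.week), str(row.trait)
            si = traits.index(s)
            cell = si * n + weeks.index(w)
            for f in fixed.factors:
                lev = str(getattr(row, f))
                key = (s, f, lev)
                if key in cpos:
                    X[apos[a], cell, cpos[key]] = 1.0
            for c in fixed.covariates:
                X[apos[a], cell, cpos[(s, "cov", c)]] = float(getattr(row, c))

    # week-nested cross-trait covariates (values of other traits)
    wide_by_trait = {}
    for s, sources in fixed.week_trait_covariates.items():
        si = traits.index(s)
        for src in sources:
            if src not in wide_by_trait:
                _, Ysrc, _ = pheno.to_wide([src], grid, animals)
                wide_by_trait[src] = Ysrc
            Ysrc = wide_by_trait[src]
            for j, w in enumerate(weeks):
                need = mask[:, si * n + j]
                vals = Ysrc[:, j]
                if np.isnan(vals[need]).any():
                    raise DesignError(
                        f"trait covariate {src!r} missing at records where "
                        f"{s!r} is observed; interpolate production traits "
                        "first (interpolate_missing) or use the multi-SAD model"
                    )
                X[:, si * n + j, cpos[(s, f"b_{src}", w)]] = np.nan_to_num(vals)

    # rank check on observed rows
    Xobs = X[mask]
    used = np.flatnonzero(np.abs(Xobs).sum(axis=0) > 0)
    r = np.linalg.matrix_rank(Xobs[:, used])
    if r < len(used):
        # identify dependent columns by greedy QR
        keepers, bad = [], []
        Q = np.zeros((Xobs.shape[0], 0))
        for k in used:
            v = Xobs[:, k].astype(float)
            vres = v - Q @ (Q.T @ v)
            if np.linalg.norm(vres) > 1e-8 * max(1.0, np.linalg.norm(v)):
                Q = np.column_stack([Q, vres / np.linalg.norm(vres)])
                keepers.append(k)
            else:
                bad.append(columns[k])
        raise DesignError(f"rank-deficient fixed effects; confounded terms: {bad}")
    if len(used) < p:
        X = X[:, :, used]
        columns = [columns[k] for k in used]

    Amat = A.submatrix(animals) if isinstance(A, RelationshipMatrix) else np.asarray(A)
    return MixedModelData(animals, tuple(traits), grid, Y, X, columns, Amat)


# ---------------------------------------------------------------------------
# parameter vector <-> SadParams
# ---------------------------------------------------------------------------

def _layout(spec: SadSpec) -> list[tuple]:
    keys: list[tuple] = []
    for s in spec.traits:
        for comp in COMPONENTS:
            bt, gv = spec.degrees[(s, comp)]
            keys += [("theta", s, comp, q) for q in range(bt + 1)]
            keys += [("logvar", s, comp, q) for q in range(gv + 1)]
    for comp in COMPONENTS:
        if spec.has_cross(comp):
            for tgt in spec.targets:
                keys += [
                    ("cross", tgt, comp, q)
                    for q in range(spec.cross_degree[comp] + 1)
                ]
    return keys


def params_to_vector(params: SadParams) -> np.ndarray:
    spec = params.spec
    out = []
    for kind, s, comp, q in _layout(spec):
        if kind == "theta":
            out.append(params.theta[(s, comp)][q])
        elif kind == "logvar":
            out.append(params.logvar[(s, comp)][q])
        else:
            out.append(params.cross[(comp, s)][q])
    return np.array(out)


def vector_to_params(spec: SadSpec, vec: np.ndarray) -> SadParams:
    vec = np.asarray(vec, dtype=float)
    theta, logvar, cross = {}, {}, {}
    i = 0
    for s in spec.traits:
        for comp in COMPONENTS:
            bt, gv = spec.degrees[(s, comp)]
            theta[(s, comp)] = vec[i:i + bt + 1]
            i += bt + 1
            logvar[(s, comp)] = vec[i:i + gv + 1]
            i += gv + 1
    for comp in COMPONENTS:
        if spec.has_cross(comp):
            for tgt in spec.targets:
                d = spec.cross_degree[comp]
                cross[(comp, tgt)] = vec[i:i + d + 1]
                i += d + 1
    if i != len(vec):
        raise ValueError("parameter vector length does not match spec")
    return SadParams(spec, theta, logvar, cross)


def parameter_names(spec: SadSpec) -> list[str]:
    return [f"{kind}:{s}:{comp}:{q}" for kind, s, comp, q in _layout(spec)]


def production_freeze_mask(spec: SadSpec) -> np.ndarray:
    """True at entries belonging to production (non-regressed) traits.

    The two-stage scheme freezes these at their single-trait estimates to
    reduce dimension and stabilise convergence.
    """
    return np.array(
        [kind != "cross" and s != spec.regressed for kind, s, comp, q in _layout(spec)]
    )


# ---------------------------------------------------------------------------
# restricted likelihood
# ---------------------------------------------------------------------------

def _reml_from_parts(M, p, logdetV, XtVX, XtVy, ytVy, XtX):
    sign, ld_xvx = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return _BAD, None
    beta = np.linalg.solve(XtVX, XtVy)
    yPy = ytVy - XtVy @ beta
    _, ld_xx = np.linalg.slogdet(XtX)
    ll = -0.5 * ((M - p) * np.log(2 * np.pi) + logdetV + ld_xvx - ld_xx + yPy)
    return ll, beta


def _loglik_eigen(data: MixedModelData, Sg, Se, return_extras=False):
    lam, U, Yt, Xt, XtX = data.eig()
    N, m = data.Y.shape
    W = lam[:, None, None] * Sg[None] + Se[None]
    try:
        ch = np.linalg.cholesky(W)
    except np.linalg.LinAlgError:
        return (_BAD, None, None) if return_extras else _BAD
    logdetV = 2.0 * np.log(np.einsum("aii->ai", ch)).sum()
    rhs = np.concatenate([Yt[:, :, None], Xt], axis=2)
    sol = np.linalg.solve(W, rhs)
    sy, sX = sol[:, :, 0], sol[:, :, 1:]
    ytVy = float(np.einsum("am,am->", Yt, sy))
    XtVy = np.einsum("amp,am->p", Xt, sy)
    XtVX = np.einsum("amp,amq->pq", Xt, sX)
    ll, beta = _reml_from_parts(N * m, data.p, logdetV, XtVX, XtVy, ytVy, XtX)
    if not return_extras:
        return ll
    if beta is None:
        return _BAD, None, None
    # V^{-1}(y - X beta) back in the original animal basis
    r_sol = sy - np.einsum("amp,p->am", sX, beta)
    Q = U @ r_sol
    return ll, beta, Q


def _loglik_dense(data: MixedModelData, Sg, Se, return_extras=False):
    N, m = data.Y.shape
    obs = data.mask.ravel()
    V = (np.kron(data.A_sub, Sg) + np.kron(np.eye(N), Se))[np.ix_(obs, obs)]
    y = data.Y.ravel()[obs]
    X = data.X.reshape(N * m, -1)[obs]
    try:
        c = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return (_BAD, None, None) if return_extras else _BAD
    logdetV = 2.0 * np.log(np.diag(c)).sum()
    rhs = np.column_stack([y, X])
    sol = np.linalg.solve(V, rhs)
    sy, sX = sol[:, 0], sol[:, 1:]
    ll, beta = _reml_from_parts(
        obs.sum(), X.shape[1], logdetV, X.T @ sX, X.T @ sy, float(y @ sy), X.T @ X
    )
    if not return_extras:
        return ll
    if beta is None:
        return _BAD, None, None
    Q = np.zeros(N * m)
    Q[obs] = sy - sX @ beta
    return ll, beta, Q.reshape(N, m)


def restricted_loglik(
    omega: np.ndarray,
    data: MixedModelData,
    A: RelationshipMatrix | None,
    spec: SadSpec,
    method: str | None = None,
) -> float:
    """REML log-likelihood at parameter vector ``omega``.

    Uses the eigen backend for complete records, the dense observed-cell
    backend otherwise (``method`` forces one).  Returns a large negative
    sentinel when the parameters leave the feasible domain.
    """
    try:
        params = vector_to_params(spec, omega)
        Sg = multi_trait_covariance(params, data.grid, GENETIC)
        Se = multi_trait_covariance(params, data.grid, ENVIRONMENTAL)
    except (ValueError, FloatingPointError, OverflowError):
        return _BAD
    if not (np.isfinite(Sg).all() and np.isfinite(Se).all()):
        return _BAD
    use = method or ("eigen" if data.complete else "dense")
    with np.errstate(over="ignore", invalid="ignore"):
        ll = (_loglik_eigen if use == "eigen" else _loglik_dense)(data, Sg, Se)
    return ll if np.isfinite(ll) else _BAD


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """A fitted SAD mixed model."""

    spec: SadSpec
    data: MixedModelData
    omega: np.ndarray
    free: np.ndarray                 # boolean mask of optimised entries
    reml_loglik: float
    converged: bool
    fixed_effects: dict              # column tuple -> estimate
    information: np.ndarray | None = None   # on free parameters
    trail: list = field(default_factory=list)
    model: str = "multi_sad"

    @property
    def params(self) -> SadParams:
        return vector_to_params(self.spec, self.omega)

    @property
    def n_free(self) -> int:
        return int(self.free.sum())

    def free_names(self) -> list[str]:
        return [nm for nm, f in zip(parameter_names(self.spec), self.free) if f]

    def covariance_of_omega(self) -> np.ndarray:
        if self.information is None:
            raise ValueError("information matrix was not computed for this fit")
        return np.linalg.pinv(self.information)

    def standard_errors(self) -> np.ndarray:
        """Delta-method SEs for the free entries of omega (full-length array,
        NaN at frozen entries)."""
        se = np.full(len(self.omega), np.nan)
        C = self.covariance_of_omega()
        se[self.free] = np.sqrt(np.clip(np.diag(C), 0.0, None))
        return se

    def sigma_g(self) -> np.ndarray:
        return multi_trait_covariance(self.params, self.data.grid, GENETIC)

    def sigma_e(self) -> np.ndarray:
        return multi_trait_covariance(self.params, self.data.grid, ENVIRONMENTAL)


def _default_start(spec: SadSpec, data: MixedModelData) -> np.ndarray:
    """Moment-flavoured start: theta 0.3, split the cell variance in half."""
    vec = []
    n = data.grid.n
    for s in spec.traits:
        si = spec.traits.index(s)
        block = data.Y[:, si * n:(si + 1) * n]
        v = np.nanvar(block) if np.isfinite(block).any() else 1.0
        v = max(v, 1e-3)
        for comp in COMPONENTS:
            bt, gv = spec.degrees[(s, comp)]
            vec += [0.3] + [0.0] * bt
            vec += [np.log(0.5 * v)] + [0.0] * gv
    for comp in COMPONENTS:
        if spec.has_cross(comp):
            for _ in spec.targets:
                vec += [0.0] * (spec.cross_degree[comp] + 1)
    return np.array(vec)


def _fd_hessian(fun, x, h=5e-4):
    k = len(x)
    H = np.zeros((k, k))
    hs = h * (1.0 + np.abs(x))
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = hs[i]
            ej = np.zeros(k); ej[j] = hs[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hs[i] * hs[j])
    return H, f0


def fit_reml(
    data: MixedModelData,
    A: RelationshipMatrix | None,
    spec: SadSpec,
    start: np.ndarray | None = None,
    frozen: np.ndarray | None = None,
    compute_information: bool = True,
    max_restarts: int = 2,
    maxiter: int = 500,
    seed: int = 0,
    method: str | None = None,
) -> FitResult:
    """Maximise the restricted likelihood by L-BFGS-B with numerical gradients.

    ``frozen`` is a boolean mask over the full parameter vector; frozen
    entries stay at their ``start`` values (the two-stage scheme fixes
    production-trait parameters at their single-trait estimates).  On
    apparent non-convergence the optimiser restarts from jittered points.
    """
    x_full = np.array(start, dtype=float) if start is not None else _default_start(spec, data)
    if len(x_full) != len(_layout(spec)):
        raise ValueError("start vector length does not match spec")
    frozen = np.zeros(len(x_full), bool) if frozen is None else np.asarray(frozen, bool)
    free = ~frozen

    def neg_ll(xf):
        x = x_full.copy()
        x[free] = xf
        return -restricted_loglik(x, data, A, spec, method=method)

    # The effect of a degree-q coefficient scales like t^q; optimising
    # z_q = c_q * s^q (s = half the time range) evens out the curvature and
    # cuts the quasi-Newton iteration count several-fold.
    t_eval = data.grid.eval_times()
    s_base = max(1.0, 0.5 * float(np.max(np.abs(t_eval))))
    scale = np.array([s_base ** k[3] for k in _layout(spec)])[free]

    def neg_ll_z(zf):
        return neg_ll(zf / scale)

    rng = np.random.default_rng(seed)
    best = None
    x0 = x_full[free].copy()
    for attempt in range(max_restarts + 1):
        res = optimize.minimize(
            neg_ll_z, x0 * scale, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res
        if np.isfinite(res.fun) and res.fun < -0.5 * _BAD:
            break
        x0 = x_full[free] + 0.1 * rng.standard_normal(free.sum())
    xhat = x_full.copy()
    xhat[free] = best.x / scale
    converged = bool(best.success and np.isfinite(best.fun) and best.fun < -0.5 * _BAD)

    info = None
    if compute_information and free.any():
        H, _ = _fd_hessian(neg_ll, xhat[free])
        info = 0.5 * (H + H.T)

    # fixed effects at the optimum
    params = vector_to_params(spec, xhat)
    Sg = multi_trait_covariance(params, data.grid, GENETIC)
    Se = multi_trait_covariance(params, data.grid, ENVIRONMENTAL)
    use = method or ("eigen" if data.complete else "dense")
    ll, beta, _ = (_loglik_eigen if use == "eigen" else _loglik_dense)(
        data, Sg, Se, return_extras=True
    )
    fixed = dict(zip(data.columns, beta)) if beta is not None else {}
    return FitResult(
        spec=spec, data=data, omega=xhat, free=free,
        reml_loglik=float(-best.fun), converged=converged,
        fixed_effects=fixed, information=info,
    )


def lrt(fit_small: FitResult, fit_big: FitResult, boundary: bool = False):
    """Likelihood-ratio test of nested SAD structures on the same data.

    Returns (statistic, df, p).  ``boundary=True`` applies the 50:50
    chi-square mixture appropriate when the extra parameter is a variance on
    its boundary; default is the naive chi-square.
    """
    if not fit_small.spec.is_nested_in(fit_big.spec):
        raise ValueError("specs are not nested")
    if fit_small.data.Y.shape != fit_big.data.Y.shape:
        raise ValueError("fits are not on the same data")
    df = fit_big.n_free - fit_small.n_free
    stat = max(0.0, 2.0 * (fit_big.reml_loglik - fit_small.reml_loglik))
    if df <= 0:
        return stat, df, 1.0
    p = float(stats.chi2.sf(stat, df))
    if boundary:
        p = 0.5 * p if stat > 0 else 1.0
    return stat, df, p


# ---------------------------------------------------------------------------
# degree selection
# ---------------------------------------------------------------------------

@dataclass
class SearchPlan:
    """Forward-stepwise plan for SAD degree selection."""

    alpha: float = 0.05
    max_theta_degree: int = 2
    max_logvar_degree: int = 2
    max_cross_degree: int = 2
    moves: tuple = (
        (GENETIC, "theta"), (GENETIC, "logvar"),
        (ENVIRONMENTAL, "theta"), (ENVIRONMENTAL, "logvar"),
    )


def _single_trait_spec(trait, degrees):
    return SadSpec(traits=(trait,), degrees={(trait, c): degrees[c] for c in COMPONENTS},
                   cross_degree={GENETIC: None, ENVIRONMENTAL: None})


def embed_start(params: SadParams, to_spec: SadSpec, base: np.ndarray) -> np.ndarray:
    """Warm start for a larger nested spec: copy every coefficient the smaller
    model shares, leave the new (higher-degree) ones at ``base`` values.

    Keeps stepwise LRT chains honest: the candidate starts at (at least) the
    incumbent's restricted likelihood, so a worse local optimum of a
    from-scratch refit can never masquerade as evidence for the extra term.
    """
    lut = dict(zip(_layout(params.spec), params_to_vector(params)))
    out = np.array(base, dtype=float)
    for i, k in enumerate(_layout(to_spec)):
        if k in lut:
            out[i] = lut[k]
    return out


def select_degrees(
    pheno: PhenotypeTable,
    A: RelationshipMatrix,
    traits: tuple[str, ...],
    grid: TimeGrid,
    fixed: FixedSpec = FixedSpec(),
    plan: SearchPlan | None = None,
    seed: int = 0,
) -> tuple[SadSpec, list]:
    """Stepwise degree selection: per-trait single-trait SAD structures first
    (alternating antedependence and innovation-variance degrees), then the
    cross-antedependence degree increased jointly across targets and
    components; each step kept only when the LRT improves at ``plan.alpha``.

    Returns the retained multi-trait spec and the decision trail.  Fit
    failures are recorded in the trail and the step skipped.
    """
    plan = plan or SearchPlan()
    trail = []
    retained: dict = {}
    single_fits: dict = {}
    for s in traits:
        degrees = {GENETIC: (0, 0), ENVIRONMENTAL: (0, 0)}
        spec = _single_trait_spec(s, degrees)
        d1 = build_design(pheno, fixed, grid, (s,), A)
        fit = fit_reml(d1, A, spec, compute_information=False, seed=seed)
        # Best-first forward selection: each round every still-live move is
        # tried and the most significant improvement is kept.  Accepting the
        # first significant move in a fixed order instead lets a genetic term
        # soak up an unmodelled environmental trend (or vice versa) simply
        # because it is tested first.  A move that comes out non-significant
        # is capped: "no further significant improvement" for that function.
        capped: set = set()
        while True:
            best = None
            for comp, kind in plan.moves:
                if (comp, kind) in capped:
                    continue
                bt, gv = degrees[comp]
                if kind == "theta":
                    if bt >= plan.max_theta_degree or grid.n < bt + 2:
                        continue
                    cand = dict(degrees); cand[comp] = (bt + 1, gv)
                else:
                    if gv >= plan.max_logvar_degree:
                        continue
                    cand = dict(degrees); cand[comp] = (bt, gv + 1)
                cspec = _single_trait_spec(s, cand)
                try:
                    cstart = embed_start(fit.params, cspec,
                                         _default_start(cspec, d1))
                    cfit = fit_reml(d1, A, cspec, start=cstart,
                                    compute_information=False, seed=seed)
                    stat, dfree, p = lrt(fit, cfit)
                except Exception as err:  # keep searching past a failed fit
                    trail.append({"trait": s, "step": (comp, kind), "error": str(err)})
                    capped.add((comp, kind))
                    continue
                trail.append({"trait": s, "step": (comp, kind), "stat": stat, "p": p})
                if p >= plan.alpha:
                    capped.add((comp, kind))
                elif best is None or p < best[0]:
                    best = (p, (comp, kind), cand, cspec, cfit)
            if best is None:
                break
            _, move, degrees, spec, fit = best
            trail.append({"trait": s, "accepted": move, "degrees": dict(degrees)})
        retained[s] = degrees
        single_fits[s] = fit
        trail.append({"trait": s, "retained": dict(degrees)})

    # stage 2: cross-antedependence degree, production parameters frozen
    def multi_spec(cd):
        return SadSpec(
            traits=traits,
            degrees={(s, c): retained[s][c] for s in traits for c in COMPONENTS},
            cross_degree={GENETIC: cd, ENVIRONMENTAL: cd},
        )

    dm = build_design(pheno, fixed, grid, traits, A)

    def start_for(spec):
        x = _default_start(spec, dm)
        keys = _layout(spec)
        for s in traits[:-1] + (traits[-1],):
            sv = params_to_vector(single_fits[s].params)
            skeys = _layout(single_fits[s].spec)
            lut = {k: v for k, v in zip(skeys, sv)}
            for i, k in enumerate(keys):
                if k[0] != "cross" and k[1] == s and k in lut:
                    x[i] = lut[k]
        return x

    cd = 0
    spec = multi_spec(cd)
    frozen = production_freeze_mask(spec)
    fit = fit_reml(dm, A, spec, start=start_for(spec), frozen=frozen,
                   compute_information=False, seed=seed)
    while cd < plan.max_cross_degree:
        cspec = multi_spec(cd + 1)
        try:
            cstart = embed_start(fit.params, cspec, start_for(cspec))
            cfit = fit_reml(dm, A, cspec, start=cstart,
                            frozen=production_freeze_mask(cspec),
                            compute_information=False, seed=seed)
            stat, dfree, p = lrt(fit, cfit)
        except Exception as err:
            trail.append({"step": ("cross", cd + 1), "error": str(err)})
            break
        trail.append({"step": ("cross", cd + 1), "stat": stat, "p": p})
        if p < plan.alpha:
            cd, spec, fit = cd + 1, cspec, cfit
        else:
            break
    trail.append({"retained_cross_degree": cd})
    return spec, trail


# ---------------------------------------------------------------------------
# BLUP and diagnostics
# ---------------------------------------------------------------------------

def blup_solve(
    fit: FitResult,
    A: RelationshipMatrix,
) -> dict:
    """BLUP of per-animal, per-trait, per-week genetic effects (and residual
    effects for phenotyped animals).

    u_hat = (A[:, phi] (x) Sigma_g) Z' V^{-1} (y - X beta_hat) — every
    pedigree animal gets a trajectory, phenotyped or not.  Returns a dict
    with ``ids``, ``tebv`` (N_all, T*n) and ``residual`` (N_pheno, T*n).
    """
    data = fit.data
    params = fit.params
    Sg = multi_trait_covariance(params, data.grid, GENETIC)
    Se = multi_trait_covariance(params, data.grid, ENVIRONMENTAL)
    use = "eigen" if data.complete else "dense"
    ll, beta, Q = (_loglik_eigen if use == "eigen" else _loglik_dense)(
        data, Sg, Se, return_extras=True
    )
    if Q is None:
        raise np.linalg.LinAlgError("V is singular at the fitted parameters")
    pos = {a: i for i, a in enumerate(A.ids)}
    idx = np.array([pos[a] for a in data.animals])
    tebv = A.values[:, idx] @ (Q @ Sg)
    resid = Q @ Se
    return {"ids": list(A.ids), "tebv": tebv, "residual": resid,
            "animals": data.animals, "traits": data.traits, "grid": data.grid}


def information_condition_number(fit: FitResult, threshold: float = 1000.0):
    """sqrt(lambda_max / lambda_min) of the information matrix.

    Returns (value, flagged) where ``flagged`` is True above ``threshold`` or
    when the matrix is not positive definite (practical identifiability
    concern).
    """
    if fit.information is None:
        raise ValueError("fit has no information matrix")
    lam = np.linalg.eigvalsh(0.5 * (fit.information + fit.information.T))
    if lam[-1] <= 0:
        return np.inf, True
    if lam[0] <= 0:
        warnings.warn("information matrix is not positive definite")
        return np.inf, True
    val = float(np.sqrt(lam[-1] / lam[0]))
    return val, val > threshold
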