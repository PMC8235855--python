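"""The two longitudinal residual-feed-intake criteria.

*Phenotypic regression model*: a single-response SAD animal model for FI with
the production traits entering the mean as week-nested covariates; the
residual-feed-intake value of an animal is the sum of its genetic and
residual effects.  The resulting criterion is genetically independent of a
production trait only in the special parameter regime
(1 - h2_P) cov(u_FI, u_P) = h2_P cov(e_FI, e_P) (the Kennedy condition).

*Multi-SAD regression model*: the joint four-trait SAD model with genetic and
environmental cross-antedependence of FI on the production traits.  RFI* is
obtained by adjusting FI at both levels with the genetic regression
coefficients, and is genetically independent of the production traits at all
time points by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import RelationshipMatrix
from .phenotypes import PhenotypeTable
from .mixed_model import (
    FitResult,
    FixedSpec,
    MixedModelData,
    build_design,
    fit_reml,
    params_to_vector,
    production_freeze_mask,
    _layout,
    _single_trait_spec,
)
from .sad import (
    COMPONENTS,
    ENVIRONMENTAL,
    GENETIC,
    SadParams,
    SadSpec,
    TimeGrid,
    multi_trait_covariance,
    rfi_star_covariances,
)

__all__ = [
    "RfiComponents",
    "fit_phenotypic_regression_model",
    "fit_multi_sad_model",
    "regression_trajectories",
    "compute_rfi_star",
    "heritability_profile",
    "genetic_correlation_matrix",
    "kennedy_gap",
]

PRODUCTION = ("ADG", "MBW", "BF")


@dataclass
class RfiComponents:
    """Per-animal, per-week genetic and environmental RFI components."""

    animals: list[str]
    weeks: list[int]
    u: np.ndarray          # (N, n)
    e: np.ndarray          # (N, n)
    model: str             # "phenotypic_regression" | "multi_sad"

    @property
    def rfi(self) -> np.ndarray:
        return self.u + self.e

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.animals):
            for j, w in enumerate(self.weeks):
                rows.append((a, w, self.model, self.u[i, j], self.e[i, j],
                             self.u[i, j] + self.e[i, j]))
        return pd.DataFrame(rows, columns=["animal", "week", "model", "u", "e", "rfi"])


def fit_phenotypic_regression_model(
    pheno: PhenotypeTable,
    A: RelationshipMatrix,
    spec: SadSpec | None = None,
    grid: TimeGrid | None = None,
    fixed: FixedSpec = FixedSpec(),
    production: tuple[str, ...] | None = None,
    **fit_kwargs,
) -> FitResult:
    """Single-response SAD model of FI with week-specific phenotypic regression
    on the production traits in the fixed part.

    Requires complete production records at every FI record (interpolate
    first); the default structure is SAD11 genetic / SAD12 environmental and
    the default covariates are whichever of ADG/MBW/BF the table contains.
    """
    grid = grid or pheno.grid()
    if spec is None:
        spec = _single_trait_spec("FI", {GENETIC: (1, 1), ENVIRONMENTAL: (1, 2)})
    if spec.traits != ("FI",):
        raise ValueError("phenotypic regression model is a single-response FI model")
    if production is None:
        present = set(pheno.traits)
        production = tuple(t for t in PRODUCTION if t in present)
    if not production:
        raise ValueError("no production traits found to regress on")
    fixed = FixedSpec(
        factors=fixed.factors,
        covariates=fixed.covariates,
        week_trait_covariates={"FI": list(production)},
    )
    data = build_design(pheno, fixed, grid, ("FI",), A)
    fit = fit_reml(data, A, spec, **fit_kwargs)
    fit.model = "phenotypic_regression"
    return fit


def fit_multi_sad_model(
    pheno: PhenotypeTable,
    A: RelationshipMatrix,
    spec: SadSpec,
    grid: TimeGrid | None = None,
    fixed: FixedSpec = FixedSpec(),
    two_stage: bool = True,
    **fit_kwargs,
) -> FitResult:
    """Joint SAD fit of the production traits and FI with cross-antedependence.

    ``two_stage=True`` first fits each production trait with its single-trait
    SAD model, then freezes those antedependence/innovation parameters in the
    joint fit (the convergence device used with the full pig dataset).
    Missing production records are simply dropped from the likelihood.
    """
    grid = grid or pheno.grid()
    data = build_design(pheno, fixed, grid, spec.traits, A)
    start = fit_kwargs.pop("start", None)
    frozen = None
    if start is None:
        from .mixed_model import _default_start
        start = _default_start(spec, data)
        keys = _layout(spec)
        # single-trait prefits seed every trait's own parameters
        for s in spec.traits:
            sspec = _single_trait_spec(
                s, {c: spec.degrees[(s, c)] for c in COMPONENTS}
            )
            d1 = build_design(pheno, fixed, grid, (s,), A)
            f1 = fit_reml(d1, A, sspec, compute_information=False,
                          seed=fit_kwargs.get("seed", 0))
            lut = dict(zip(_layout(sspec), params_to_vector(f1.params)))
            for i, k in enumerate(keys):
                if k[0] != "cross" and k[1] == s and k in lut:
                    start[i] = lut[k]
        # cross coefficients seeded by week-wise phenotypic regressions
        bstart = _moment_cross_start(pheno, spec, grid)
        for i, k in enumerate(keys):
            kind, tgt, comp, q = k
            if kind == "cross" and (comp, tgt, q) in bstart:
                start[i] = bstart[(comp, tgt, q)]
    if two_stage:
        frozen = production_freeze_mask(spec)
    fit = fit_reml(data, A, spec, start=start, frozen=frozen, **fit_kwargs)
    fit.model = "multi_sad"
    return fit


def _moment_cross_start(pheno: PhenotypeTable, spec: SadSpec, grid: TimeGrid) -> dict:
    """Week-wise phenotypic regression of FI on each production trait,
    summarised by a polynomial of the spec's cross degree — a cheap, sensible
    start for both the genetic and environmental cross coefficients."""
    out = {}
    _, Y, _ = pheno.to_wide(list(spec.traits), grid)
    n = grid.n
    fi = (len(spec.traits) - 1) * n
    t_eval = grid.eval_times()
    for ti, tgt in enumerate(spec.targets):
        bw = np.full(n, np.nan)
        for j in range(n):
            x = Y[:, ti * n + j]
            y = Y[:, fi + j]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() >= 10 and np.var(x[ok]) > 0:
                bw[j] = np.cov(x[ok], y[ok])[0, 1] / np.var(x[ok])
        ok = np.isfinite(bw)
        for comp in COMPONENTS:
            d = spec.cross_degree[comp]
            if d is None:
                continue
            if ok.sum() >= d + 1:
                coef = np.polyfit(t_eval[ok], bw[ok], d)[::-1]
            else:
                coef = np.zeros(d + 1)
            for q, c in enumerate(coef):
                out[(comp, tgt, q)] = float(c)
    return out


def regression_trajectories(fit: FitResult) -> pd.DataFrame:
    """Week-by-week regression-coefficient trajectories with delta-method SEs.

    For a multi-SAD fit: the genetic and environmental cross-antedependence
    polynomials evaluated at each week, plus the covariance-implied phenotypic
    coefficient b_p = cov_p(s_j, FI_j) / var_p(s_j) from Sigma_g + Sigma_e.
    For the phenotypic-regression model: the estimated week-nested fixed
    covariate slopes.
    """
    grid = fit.data.grid
    weeks = [int(t) for t in grid.times]
    rows = []
    if fit.model == "phenotypic_regression":
        for (s, name, w), est in fit.fixed_effects.items():
            if name.startswith("b_"):
                rows.append({"trait": name[2:], "week": w, "b_phenotypic": est})
        return pd.DataFrame(rows).sort_values(["trait", "week"]).reset_index(drop=True)

    params = fit.params
    spec = fit.spec
    Sg = multi_trait_covariance(params, grid, GENETIC)
    Se = multi_trait_covariance(params, grid, ENVIRONMENTAL)
    Sp = Sg + Se
    n = grid.n
    fi = (len(spec.traits) - 1) * n
    se_full = None
    if fit.information is not None:
        C = fit.covariance_of_omega()
        se_lut = {}
        free_keys = [k for k, f in zip(_layout(spec), fit.free) if f]
        Cd = np.sqrt(np.clip(np.diag(C), 0, None))
        cov_lut = {k: i for i, k in enumerate(free_keys)}
        se_full = (free_keys, C)
    t_eval = grid.eval_times()
    implied = _implied_cross_coefficients(Sg, len(spec.traits), n)
    for ti, s in enumerate(spec.targets):
        for j, w in enumerate(weeks):
            row = {"trait": s, "week": w}
            row["b_phenotypic"] = Sp[ti * n + j, fi + j] / Sp[ti * n + j, ti * n + j]
            row["b_u_implied"] = implied[ti, j]
            for comp, tag in ((GENETIC, "b_u"), (ENVIRONMENTAL, "b_e")):
                if spec.has_cross(comp):
                    b = params.cross_at(comp, s, grid)[j]
                    row[tag] = b
                    if se_full is not None:
                        keys, C = se_full
                        grad = np.array([
                            t_eval[j] ** k[3]
                            if (k[0] == "cross" and k[1] == s and k[2] == comp)
                            else 0.0
                            for k in keys
                        ])
                        row[tag + "_se"] = float(np.sqrt(max(grad @ C @ grad, 0.0)))
            rows.append(row)
    return pd.DataFrame(rows)


def compute_rfi_star(
    fit_or_params,
    effects: dict,
    coefficients: str = GENETIC,
) -> RfiComponents:
    """RFI* components by the forward recursions.

    ``effects`` holds per-animal trait-by-week effect arrays: keys ``ids``,
    ``genetic`` and ``environmental``, each (N, T*n) in trait-major order
    (BLUP output or simulated truth).  The genetic recursion always uses the
    genetic cross coefficients; ``coefficients`` selects those used for the
    environmental adjustment — ``"genetic"`` follows the defining equations
    (independence at the genetic level), ``"environmental"`` gives the
    variant that is independent at the phenotypic level too.
    """
    params = fit_or_params.params if isinstance(fit_or_params, FitResult) else fit_or_params
    spec = params.spec
    grid = (fit_or_params.data.grid if isinstance(fit_or_params, FitResult)
            else effects.get("grid"))
    if grid is None:
        raise ValueError("pass a FitResult or include 'grid' in effects")
    n = grid.n
    T = len(spec.traits)
    fi = (T - 1) * n
    out = {}
    for comp, coefs in ((GENETIC, GENETIC), (ENVIRONMENTAL, coefficients)):
        eff = np.asarray(effects[comp], dtype=float)
        th = params.theta_at(spec.regressed, comp, grid)
        b = {t: params.cross_at(coefs, t, grid) for t in spec.targets} \
            if spec.has_cross(coefs) else {t: np.zeros(n) for t in spec.targets}
        xFI = eff[:, fi:fi + n]
        star = np.zeros_like(xFI)
        for j in range(n):
            v = xFI[:, j].copy()
            if j > 0:
                v += th[j] * (star[:, j - 1] - xFI[:, j - 1])
            for ti, t in enumerate(spec.targets):
                v -= b[t][j] * eff[:, ti * n + j]
            star[:, j] = v
        out[comp] = star
    return RfiComponents(
        animals=list(effects["ids"]),
        weeks=[int(t) for t in grid.times],
        u=out[GENETIC],
        e=out[ENVIRONMENTAL],
        model="multi_sad",
    )


def _implied_cross_coefficients(Sg: np.ndarray, T: int, n: int) -> np.ndarray:
    """Genetic cross coefficients implied by a joint genetic covariance.

    The marginal ratio cov(u_s,j, u_FI,j)/var(u_s,j) equals the
    cross-antedependence parameter only at the first week: for later weeks the
    lagged FI effect contributes.  The exact identity is the *partial*
    regression of u_FI,j on the contemporaneous production effects and
    u_FI,j-1 — the defining recursion itself — so that is what is computed
    here.  Returns (T-1, n).
    """
    fi = (T - 1) * n
    out = np.zeros((T - 1, n))
    for j in range(n):
        reg = [ti * n + j for ti in range(T - 1)]
        if j > 0:
            reg.append(fi + j - 1)
        reg = np.array(reg)
        coef = np.linalg.solve(Sg[np.ix_(reg, reg)], Sg[reg, fi + j])
        out[:, j] = coef[: T - 1]
    return out


def rfi_star_from_blup(fit: FitResult, blup: dict,
                       coefficients: str = GENETIC) -> RfiComponents:
    """RFI* for the phenotyped animals from a BLUP solution.

    Genetic effects are the TEBV; environmental effects are the BLUPs of the
    residual trait effects (their conditional expectations at unobserved
    cells, which is where missing records are silently completed).
    """
    pos = {a: i for i, a in enumerate(blup["ids"])}
    idx = [pos[a] for a in blup["animals"]]
    effects = {
        "ids": blup["animals"],
        GENETIC: blup["tebv"][idx],
        ENVIRONMENTAL: blup["residual"],
        "grid": blup["grid"],
    }
    return compute_rfi_star(fit, effects, coefficients=coefficients)


def heritability_profile(fit: FitResult) -> pd.DataFrame:
    """Weekly heritability of RFI with delta-method SEs.

    Multi-SAD: h2_j = G*_jj / (G*_jj + P*_FI,jj); phenotypic-regression model:
    G_jj / (G_jj + P_jj).
    """
    grid = fit.data.grid
    params = fit.params
    n = grid.n

    def h2_of(omega):
        p = params.__class__(fit.spec, **_params_dicts(fit.spec, omega))
        if fit.model == "phenotypic_regression":
            g = np.diag(multi_trait_covariance(p, grid, GENETIC))
            e = np.diag(multi_trait_covariance(p, grid, ENVIRONMENTAL))
            return g / (g + e)
        cs = rfi_star_covariances(p, grid)
        fi = (len(fit.spec.traits) - 1) * n
        g = np.diag(cs.genetic)
        e = np.diag(cs.environmental)[fi:fi + n]
        return g / (g + e)

    h2 = h2_of(fit.omega)
    se = np.full(n, np.nan)
    if fit.information is not None:
        C = fit.covariance_of_omega()
        free_idx = np.flatnonzero(fit.free)
        J = np.zeros((n, len(free_idx)))
        h = 1e-5
        for k, fi_k in enumerate(free_idx):
            om = fit.omega.copy()
            om[fi_k] += h
            up = h2_of(om)
            om[fi_k] -= 2 * h
            dn = h2_of(om)
            J[:, k] = (up - dn) / (2 * h)
        se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", J, C, J), 0, None))
    return pd.DataFrame({
        "week": [int(t) for t in grid.times],
        "h2": h2,
        "se": se,
        "model": fit.model,
    })


def _params_dicts(spec: SadSpec, omega):
    from .mixed_model import vector_to_params
    p = vector_to_params(spec, omega)
    return {"theta": p.theta, "logvar": p.logvar, "cross": p.cross}


def genetic_correlation_matrix(G: np.ndarray) -> np.ndarray:
    """Correlation normalisation of a PD genetic covariance matrix."""
    d = np.diag(G)
    if np.any(d <= 0):
        raise ValueError("zero or negative diagonal entry: correlation undefined")
    s = 1.0 / np.sqrt(d)
    R = G * np.outer(s, s)
    np.fill_diagonal(R, 1.0)
    return R


def kennedy_gap(params: SadParams, grid: TimeGrid, trait: str, week: int) -> float:
    """(1 - h2_P) cov_u(FI, P) - h2_P cov_e(FI, P) at one trait and week.

    Zero exactly when the phenotypic-regression RFI is genetically
    independent of that production trait at that week.
    """
    spec = params.spec
    n = grid.n
    j = [int(t) for t in grid.times].index(int(week))
    ti = spec.traits.index(trait)
    fi = (len(spec.traits) - 1) * n
    Sg = multi_trait_covariance(params, grid, GENETIC)
    Se = multi_trait_covariance(params, grid, ENVIRONMENTAL)
    gP = Sg[ti * n + j, ti * n + j]
    eP = Se[ti * n + j, ti * n + j]
    h2 = gP / (gP + eP)
    cov_u = Sg[fi + j, ti * n + j]
    cov_e = Se[fi + j, ti * n + j]
    return float((1.0 - h2) * cov_u - h2 * cov_e)
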