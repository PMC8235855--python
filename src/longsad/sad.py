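"""Structured-antedependence (SAD) covariance functions.

A first-order SAD model writes a random effect at measurement time t_j as a
regression on its own value at t_{j-1} plus an innovation:

    u_j = theta_j * u_{j-1} + eps_j,          var(eps_j) = sigma2_j,

with the antedependence parameter theta and the log innovation variance both
polynomial functions of time.  Stacking times gives the factorisation
Sigma^{-1} = L' D^{-1} L with L unit lower triangular (negated antedependence
parameters on the first subdiagonal) and D the diagonal of innovation
variances.

The multi-trait extension adds *cross-antedependence*: the regressed trait
(feed intake, always last in the trait order) additionally regresses on the
contemporaneous random effects of the production traits, with coefficients
b_s(t) that are again polynomials of time, separately for the genetic and
environmental components.  Production traits are mutually independent; their
covariances with the regressed trait arise only through the cross terms.

From a fitted multi-trait model the residual-feed-intake construction needs:

* ``G*`` — genetic covariance of RFI*, a plain SAD matrix built from the
  regressed trait's genetic antedependence and innovation parameters only;
* ``P* = B P_T B'`` — environmental covariance of RFI* and production traits,
  where ``P_T`` is the joint environmental covariance and ``B`` applies the
  unrolled e*-recursion (genetic cross coefficients by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

GENETIC = "genetic"
ENVIRONMENTAL = "environmental"
COMPONENTS = (GENETIC, ENVIRONMENTAL)

__all__ = [
    "GENETIC",
    "ENVIRONMENTAL",
    "COMPONENTS",
    "TimeGrid",
    "PolyFunction",
    "eval_poly",
    "SadSpec",
    "SadParams",
    "CovarianceSet",
    "single_trait_factors",
    "covariance_from_factors",
    "joint_factors",
    "multi_trait_covariance",
    "build_B",
    "rfi_star_covariances",
]


@dataclass(frozen=True)
class TimeGrid:
    """Ordered measurement times (week indices by default).

    ``rescale=True`` evaluates the polynomial time functions on an affine map
    of the grid onto [-1, 1] (better conditioned for high degrees); the default
    uses raw week indices 1..n.
    """

    times: tuple[float, ...]
    rescale: bool = False

    def __post_init__(self):
        t = tuple(float(x) for x in self.times)
        if len(t) < 1 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("times must be strictly increasing and non-empty")
        object.__setattr__(self, "times", t)

    @classmethod
    def weeks(cls, n: int, rescale: bool = False) -> "TimeGrid":
        return cls(tuple(range(1, n + 1)), rescale)

    @property
    def n(self) -> int:
        return len(self.times)

    def eval_times(self) -> np.ndarray:
        t = np.asarray(self.times)
        if self.rescale and self.n > 1:
            lo, hi = t[0], t[-1]
            return 2.0 * (t - lo) / (hi - lo) - 1.0
        return t


@dataclass(frozen=True)
class PolyFunction:
    """Polynomial of time with an identity or exp link."""

    coefficients: tuple[float, ...]
    link: str = "identity"

    def __post_init__(self):
        if self.link not in ("identity", "exp"):
            raise ValueError(f"unknown link {self.link!r}")
        object.__setattr__(
            self, "coefficients", tuple(float(c) for c in self.coefficients)
        )

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        val = np.zeros_like(t)
        for c in reversed(self.coefficients):
            val = val * t + c
        return np.exp(val) if self.link == "exp" else val


def eval_poly(f: PolyFunction, t):
    """Evaluate a polynomial time function (identity or exp link) at t."""
    return f(t)


@dataclass(frozen=True)
class SadSpec:
    """Model structure: polynomial degrees per trait/component.

    ``degrees[(trait, component)] = (theta_degree, logvar_degree)`` — the
    SAD "beta gamma" notation (SAD11 = degree 1 for both).  ``cross_degree``
    maps a component to the shared polynomial degree of the cross-antedependence
    coefficients of the last trait on every earlier trait, or ``None`` for no
    cross terms in that component.  The regressed trait is always last.
    """

    traits: tuple[str, ...]
    degrees: dict = field(default_factory=dict)
    cross_degree: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "traits", tuple(self.traits))
        degs = dict(self.degrees)
        for s in self.traits:
            for comp in COMPONENTS:
                bt, gv = degs.get((s, comp), (0, 0))
                if bt < 0 or gv < 0:
                    raise ValueError("polynomial degrees must be >= 0")
                degs[(s, comp)] = (int(bt), int(gv))
        object.__setattr__(self, "degrees", degs)
        cd = {c: self.cross_degree.get(c) for c in COMPONENTS}
        object.__setattr__(self, "cross_degree", cd)

    @property
    def regressed(self) -> str:
        return self.traits[-1]

    @property
    def targets(self) -> tuple[str, ...]:
        return self.traits[:-1]

    def has_cross(self, component: str) -> bool:
        return self.cross_degree[component] is not None

    def n_parameters(self) -> int:
        k = sum(bt + gv + 2 for bt, gv in self.degrees.values())
        for comp in COMPONENTS:
            if self.has_cross(comp):
                k += (self.cross_degree[comp] + 1) * len(self.targets)
        return k

    def is_nested_in(self, other: "SadSpec") -> bool:
        if self.traits != other.traits:
            return False
        for key, (bt, gv) in self.degrees.items():
            obt, ogv = other.degrees[key]
            if bt > obt or gv > ogv:
                return False
        for comp in COMPONENTS:
            a, b = self.cross_degree[comp], other.cross_degree[comp]
            if a is not None and (b is None or a > b):
                return False
        return True


@dataclass
class SadParams:
    """Polynomial coefficients conforming to a :class:`SadSpec`.

    ``theta[(trait, comp)]`` and ``logvar[(trait, comp)]`` hold identity- and
    log-scale coefficient tuples; ``cross[(comp, target)]`` the coefficients of
    the regressed trait's cross-antedependence on ``target``.
    """

    spec: SadSpec
    theta: dict
    logvar: dict
    cross: dict = field(default_factory=dict)

    def __post_init__(self):
        for s in self.spec.traits:
            for comp in COMPONENTS:
                bt, gv = self.spec.degrees[(s, comp)]
                th = np.asarray(self.theta[(s, comp)], dtype=float)
                lv = np.asarray(self.logvar[(s, comp)], dtype=float)
                if th.shape != (bt + 1,) or lv.shape != (gv + 1,):
                    raise ValueError(
                        f"coefficient lengths for {s}/{comp} do not match spec"
                    )
                self.theta[(s, comp)] = th
                self.logvar[(s, comp)] = lv
        for comp in COMPONENTS:
            if self.spec.has_cross(comp):
                d = self.spec.cross_degree[comp]
                for tgt in self.spec.targets:
                    cc = np.asarray(self.cross[(comp, tgt)], dtype=float)
                    if cc.shape != (d + 1,):
                        raise ValueError(
                            f"cross coefficient length for {comp}/{tgt} "
                            "does not match spec"
                        )
                    self.cross[(comp, tgt)] = cc

    # --- evaluation on a grid -------------------------------------------
    def theta_fn(self, trait: str, component: str) -> PolyFunction:
        return PolyFunction(tuple(self.theta[(trait, component)]))

    def var_fn(self, trait: str, component: str) -> PolyFunction:
        return PolyFunction(tuple(self.logvar[(trait, component)]), link="exp")

    def cross_fn(self, component: str, target: str) -> PolyFunction:
        return PolyFunction(tuple(self.cross[(component, target)]))

    def theta_at(self, trait, component, grid: TimeGrid) -> np.ndarray:
        return self.theta_fn(trait, component)(grid.eval_times())

    def var_at(self, trait, component, grid: TimeGrid) -> np.ndarray:
        return self.var_fn(trait, component)(grid.eval_times())

    def cross_at(self, component, target, grid: TimeGrid) -> np.ndarray:
        return self.cross_fn(component, target)(grid.eval_times())


@dataclass
class CovarianceSet:
    """Genetic and environmental covariance matrices with their factors."""

    traits: tuple[str, ...]
    grid: TimeGrid
    genetic: np.ndarray
    environmental: np.ndarray
    factors: dict = field(default_factory=dict)

    def labels(self) -> list[str]:
        return [f"{s}:{int(t)}" for s in self.traits for t in self.grid.times]

    def block(self, matrix: np.ndarray, trait_a: str, trait_b: str) -> np.ndarray:
        n = self.grid.n
        ia = self.traits.index(trait_a) * n
        ib = self.traits.index(trait_b) * n
        return matrix[ia:ia + n, ib:ib + n]


def single_trait_factors(
    params: SadParams, grid: TimeGrid, trait: str, component: str
) -> tuple[np.ndarray, np.ndarray]:
    """(L, d): unit-lower-triangular factor and innovation-variance diagonal.

    L has -theta_j on the first subdiagonal for rows 2..n (the first time
    point has no antedependence term: u_1 = eps_1).
    """
    n = grid.n
    th = params.theta_at(trait, component, grid)
    d = params.var_at(trait, component, grid)
    L = np.eye(n)
    idx = np.arange(1, n)
    L[idx, idx - 1] = -th[1:]
    return L, d


def covariance_from_factors(L: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Covariance Sigma with Sigma^{-1} = L' D^{-1} L, computed by solves.

    Equals the covariance implied by the defining recursion
    u = L^{-1} eps with var(eps) = diag(d).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("innovation variances must be strictly positive")
    M = solve_triangular(L, np.diag(np.sqrt(d)), lower=True)
    return M @ M.T


def joint_factors(
    params: SadParams, grid: TimeGrid, component: str
) -> tuple[np.ndarray, np.ndarray]:
    """Joint (T*n) regression operator L and innovation diagonal d.

    Cell ordering is trait-major: trait s occupies rows s*n .. s*n+n-1 in the
    spec's trait order (regressed trait last).  Within-trait rows carry the
    lag-1 antedependence entry; rows of the regressed trait additionally carry
    the contemporaneous cross-antedependence entries on each production trait.
    """
    spec = params.spec
    n = grid.n
    T = len(spec.traits)
    m = T * n
    L = np.eye(m)
    d = np.empty(m)
    for si, s in enumerate(spec.traits):
        th = params.theta_at(s, component, grid)
        d[si * n:(si + 1) * n] = params.var_at(s, component, grid)
        for j in range(1, n):
            L[si * n + j, si * n + j - 1] = -th[j]
    if spec.has_cross(component):
        fi = (T - 1) * n
        for ti, tgt in enumerate(spec.targets):
            b = params.cross_at(component, tgt, grid)
            for j in range(n):
                L[fi + j, ti * n + j] = -b[j]
    return L, d


def multi_trait_covariance(
    params: SadParams, grid: TimeGrid, component: str
) -> np.ndarray:
    """Joint covariance of the stacked trait-by-time random effects."""
    L, d = joint_factors(params, grid, component)
    return covariance_from_factors(L, d)


def build_B(
    params: SadParams, grid: TimeGrid, coefficients: str = GENETIC
) -> np.ndarray:
    """Regression operator B mapping joint environmental effects to RFI* space.

    Identity blocks for the production traits; the last-trait row blocks hold
    the unrolled e*-recursion: entry (row j, col m), m <= j, equals
    -(prod_{k=m+1}^{j} theta_{e,FI,k}) * b_{u,s,m}, i.e. -b_{u,s,j} on the
    block diagonal.  ``coefficients`` selects which cross coefficients are
    removed: ``"genetic"`` (the default RFI* construction) or
    ``"environmental"`` (the variant that is also phenotypically independent).
    """
    if coefficients not in COMPONENTS:
        raise ValueError("coefficients must be 'genetic' or 'environmental'")
    spec = params.spec
    n = grid.n
    T = len(spec.traits)
    m = T * n
    B = np.eye(m)
    if not spec.has_cross(coefficients):
        return B
    fi = (T - 1) * n
    th_e = params.theta_at(spec.regressed, ENVIRONMENTAL, grid)
    for ti, tgt in enumerate(spec.targets):
        b = params.cross_at(coefficients, tgt, grid)
        for j in range(n):
            prod = 1.0
            B[fi + j, ti * n + j] = -b[j]
            for mm in range(j - 1, -1, -1):
                prod *= th_e[mm + 1]
                B[fi + j, ti * n + mm] = -prod * b[mm]
    return B


def rfi_star_covariances(
    params: SadParams, grid: TimeGrid, coefficients: str = GENETIC
) -> CovarianceSet:
    """Covariances of the multi-SAD RFI* criterion.

    G* uses only the regressed trait's genetic antedependence and innovation
    parameters (cross-antedependence excluded); P* = B P_T B' transforms the
    joint environmental covariance.  The returned environmental matrix is the
    full transformed joint matrix (production blocks unchanged, last-trait
    block = environmental covariance of RFI*).
    """
    spec = params.spec
    Ls, ds = single_trait_factors(params, grid, spec.regressed, GENETIC)
    G_star = covariance_from_factors(Ls, ds)
    P_T = multi_trait_covariance(params, grid, ENVIRONMENTAL)
    B = build_B(params, grid, coefficients)
    P_star = B @ P_T @ B.T
    return CovarianceSet(
        traits=spec.traits,
        grid=grid,
        genetic=G_star,
        environmental=P_star,
        factors={"L_star": Ls, "d_star": ds, "B": B, "P_T": P_T},
    )
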