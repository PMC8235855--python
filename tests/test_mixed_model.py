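import numpy as np
import pandas as pd
import pytest
from scipy.linalg import null_space

from longsad import (
    ENVIRONMENTAL,
    GENETIC,
    FixedSpec,
    PhenotypeTable,
    SadSpec,
    TimeGrid,
    build_A,
    build_design,
    fit_reml,
    information_condition_number,
    lrt,
    multi_trait_covariance,
    params_to_vector,
    restricted_loglik,
    vector_to_params,
)
from longsad.mixed_model import DesignError, _single_trait_spec, blup_solve
from longsad.simulate import (
    assemble_phenotypes,
    default_config,
    simulate_dataset,
    simulate_effects,
    simulate_pedigree,
)

from conftest import two_trait_spec


def toy_dataset(seed=0, n_gen=2, n_sires=2, n_dams=3, litter=2, weeks=2,
                params=None, complete=True):
    cfg = default_config(n_generations=n_gen, n_sires=n_sires, n_dams=n_dams,
                         litter_size=litter, grid=TimeGrid.weeks(weeks), seed=seed)
    if params is not None:
        cfg.params = params
        cfg.trait_means = {s: cfg.trait_means.get(s, (0.0,) * 10)[:weeks]
                           for s in params.spec.traits}
    ped, pheno, eff = simulate_dataset(cfg, complete=complete)
    return cfg, ped, pheno, eff


def projection_reml(data, Sg, Se):
    """Independent dense REML criterion via an explicit null-space projection."""
    N, m = data.Y.shape
    obs = data.mask.ravel()
    V = (np.kron(data.A_sub, Sg) + np.kron(np.eye(N), Se))[np.ix_(obs, obs)]
    X = data.X.reshape(N * m, -1)[obs]
    y = data.Y.ravel()[obs]
    K = null_space(X.T)
    KVK = K.T @ V @ K
    Ky = K.T @ y
    _, ld = np.linalg.slogdet(KVK)
    return -0.5 * (K.shape[1] * np.log(2 * np.pi) + ld
                   + Ky @ np.linalg.solve(KVK, Ky))


class TestBuildDesign:
    def test_intercept_only_columns(self):
        df = pd.DataFrame({
            "animal": ["a", "a", "b", "b"], "week": [1, 2, 1, 2],
            "trait": ["FI"] * 4, "value": [1.0, 2, 3, 4],
        })
        data = build_design(PhenotypeTable(df), FixedSpec(), TimeGrid.weeks(2),
                            ("FI",), np.eye(2))
        assert data.X.shape == (2, 2, 2)
        assert data.columns == [("FI", "week", 1), ("FI", "week", 2)]

    def test_factor_treatment_coding(self):
        df = pd.DataFrame({
            "animal": list("abcdef"), "week": [1] * 6, "trait": ["FI"] * 6,
            "value": np.arange(6.0), "sex": ["m", "f", "x", "m", "f", "x"],
        })
        data = build_design(PhenotypeTable(df), FixedSpec(factors=("sex",)),
                            TimeGrid.weeks(1), ("FI",), np.eye(6))
        # intercept + 2 contrast columns for 3 levels
        assert data.p == 3

    def test_confounded_factors_raise(self):
        df = pd.DataFrame({
            "animal": list("abcd"), "week": [1] * 4, "trait": ["FI"] * 4,
            "value": np.arange(4.0),
            "pen": ["p1", "p1", "p2", "p2"], "batch": ["b1", "b1", "b2", "b2"],
        })
        with pytest.raises(DesignError, match="confounded"):
            build_design(PhenotypeTable(df), FixedSpec(factors=("pen", "batch")),
                         TimeGrid.weeks(1), ("FI",), np.eye(4))

    def test_unknown_column_raises(self):
        df = pd.DataFrame({"animal": ["a"], "week": [1], "trait": ["FI"],
                           "value": [1.0]})
        with pytest.raises(DesignError, match="unknown"):
            build_design(PhenotypeTable(df), FixedSpec(factors=("herd",)),
                         TimeGrid.weeks(1), ("FI",), np.eye(1))


class TestRestrictedLoglik:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_projection_oracle(self, seed, two_trait_params):
        cfg, ped, pheno, _ = toy_dataset(seed=seed, weeks=2,
                                         params=two_trait_params)
        A = build_A(ped)
        data = build_design(pheno, FixedSpec(), cfg.grid,
                            two_trait_params.spec.traits, A)
        rng = np.random.default_rng(seed)
        for _ in range(10):
            base = params_to_vector(two_trait_params)
            om = base + 0.2 * rng.standard_normal(len(base))
            p = vector_to_params(two_trait_params.spec, om)
            Sg = multi_trait_covariance(p, cfg.grid, GENETIC)
            Se = multi_trait_covariance(p, cfg.grid, ENVIRONMENTAL)
            ll = restricted_loglik(om, data, A, two_trait_params.spec)
            assert ll == pytest.approx(projection_reml(data, Sg, Se), abs=1e-8)

    def test_eigen_equals_dense(self, two_trait_params):
        cfg, ped, pheno, _ = toy_dataset(seed=3, weeks=3, params=two_trait_params)
        A = build_A(ped)
        data = build_design(pheno, FixedSpec(), cfg.grid,
                            two_trait_params.spec.traits, A)
        om = params_to_vector(two_trait_params)
        ll_e = restricted_loglik(om, data, A, two_trait_params.spec, method="eigen")
        ll_d = restricted_loglik(om, data, A, two_trait_params.spec, method="dense")
        assert ll_e == pytest.approx(ll_d, abs=1e-9)

    def test_translation_invariance(self, two_trait_params):
        """Adding a constant in the span of X leaves REML unchanged."""
        cfg, ped, pheno, _ = toy_dataset(seed=4, weeks=2, params=two_trait_params)
        A = build_A(ped)
        spec = two_trait_params.spec
        data = build_design(pheno, FixedSpec(), cfg.grid, spec.traits, A)
        om = params_to_vector(two_trait_params)
        ll0 = restricted_loglik(om, data, A, spec)
        shifted = pheno.data.copy()
        shifted.loc[shifted["trait"] == "FI", "value"] += 57.0
        data2 = build_design(PhenotypeTable(shifted), FixedSpec(), cfg.grid,
                             spec.traits, A)
        assert restricted_loglik(om, data2, A, spec) == pytest.approx(ll0, abs=1e-7)

    def test_iid_closed_form(self):
        """Single trait/week, A = I, no genetic variance: REML of the iid
        Gaussian location model, -((n-1)/2)(log 2pi s2) - ... with the usual
        (n-1) denominator."""
        rng = np.random.default_rng(0)
        y = rng.normal(5.0, 2.0, 40)
        df = pd.DataFrame({"animal": [f"a{i}" for i in range(40)],
                           "week": 1, "trait": ["FI"] * 40, "value": y})
        spec = _single_trait_spec("FI", {GENETIC: (0, 0), ENVIRONMENTAL: (0, 0)})
        data = build_design(PhenotypeTable(df), FixedSpec(), TimeGrid.weeks(1),
                            ("FI",), np.eye(40))
        s2 = 3.7
        tiny = 1e-10
        om = np.array([0.0, np.log(tiny), 0.0, np.log(s2)])
        ll = restricted_loglik(om, data, None, spec, method="dense")
        n = 40
        rss = np.sum((y - y.mean()) ** 2)
        expected = -0.5 * ((n - 1) * np.log(2 * np.pi * s2) + np.log(n)
                           - np.log(n) + rss / s2)
        assert ll == pytest.approx(expected, abs=1e-5)

    def test_contrast_coding_invariance(self):
        """Relabelling factor levels (changing the reference level) leaves the
        restricted likelihood unchanged."""
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "animal": [f"a{i}" for i in range(30)], "week": 1,
            "trait": ["FI"] * 30, "value": rng.normal(size=30),
            "sex": ["m", "f", "c"] * 10,
        })
        spec = _single_trait_spec("FI", {GENETIC: (0, 0), ENVIRONMENTAL: (0, 0)})
        om = np.array([0.0, np.log(0.5), 0.0, np.log(1.2)])
        lls = []
        for relabel in ({}, {"m": "zz"}):
            d = df.copy()
            d["sex"] = d["sex"].replace(relabel)
            data = build_design(PhenotypeTable(d), FixedSpec(factors=("sex",)),
                                TimeGrid.weeks(1), ("FI",), np.eye(30))
            lls.append(restricted_loglik(om, data, None, spec, method="dense"))
        assert lls[0] == pytest.approx(lls[1], abs=1e-8)


class TestFitReml:
    def test_refit_from_truth_does_not_decrease(self, two_trait_params):
        cfg, ped, pheno, _ = toy_dataset(seed=6, n_sires=5, n_dams=10,
                                         litter=3, weeks=3,
                                         params=two_trait_params)
        A = build_A(ped)
        spec = two_trait_params.spec
        data = build_design(pheno, FixedSpec(), cfg.grid, spec.traits, A)
        om = params_to_vector(two_trait_params)
        ll0 = restricted_loglik(om, data, A, spec)
        fit = fit_reml(data, A, spec, start=om, compute_information=False)
        assert fit.reml_loglik >= ll0 - 1e-6

    def test_single_trait_recovery(self):
        """SAD00, 300 unrelated genotyped-by-pedigree animals: estimates land
        within 3 model SEs of truth."""
        spec = _single_trait_spec("FI", {GENETIC: (0, 0), ENVIRONMENTAL: (0, 0)})
        from longsad import SadParams
        p = SadParams(spec,
                      theta={("FI", GENETIC): (0.5,), ("FI", ENVIRONMENTAL): (0.3,)},
                      logvar={("FI", GENETIC): (0.0,), ("FI", ENVIRONMENTAL): (0.0,)})
        cfg = default_config(n_generations=2, n_sires=20, n_dams=50,
                             litter_size=4, grid=TimeGrid.weeks(8), seed=13)
        cfg.params = p
        cfg.trait_means = {"FI": (0.0,) * 8}
        ped = simulate_pedigree(cfg)
        eff = simulate_effects(ped, p, cfg.grid, 14)
        pheno = assemble_phenotypes(eff, cfg)
        A = build_A(ped)
        data = build_design(pheno, FixedSpec(), cfg.grid, ("FI",), A)
        fit = fit_reml(data, A, spec, seed=2)
        se = fit.standard_errors()
        truth = params_to_vector(p)
        z = (fit.omega - truth) / se
        assert np.all(np.abs(z) < 3.5)

    def test_frozen_parameters_stay_fixed(self, two_trait_params):
        cfg, ped, pheno, _ = toy_dataset(seed=8, weeks=2, params=two_trait_params)
        A = build_A(ped)
        spec = two_trait_params.spec
        data = build_design(pheno, FixedSpec(), cfg.grid, spec.traits, A)
        om = params_to_vector(two_trait_params)
        frozen = np.zeros(len(om), bool)
        frozen[:4] = True
        fit = fit_reml(data, A, spec, start=om, frozen=frozen,
                       compute_information=False)
        np.testing.assert_allclose(fit.omega[:4], om[:4])


class TestLrt:
    def test_identical_fits(self, two_trait_params):
        cfg, ped, pheno, _ = toy_dataset(seed=9, weeks=2, params=two_trait_params)
        A = build_A(ped)
        spec = two_trait_params.spec
        data = build_design(pheno, FixedSpec(), cfg.grid, spec.traits, A)
        fit = fit_reml(data, A, spec, start=params_to_vector(two_trait_params),
                       compute_information=False, maxiter=5)
        stat, df, p = lrt(fit, fit)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_non_nested_rejected(self, two_trait_params):
        cfg, ped, pheno, _ = toy_dataset(seed=9, weeks=2, params=two_trait_params)
        A = build_A(ped)
        data = build_design(pheno, FixedSpec(), cfg.grid,
                            two_trait_params.spec.traits, A)
        fit = fit_reml(data, A, two_trait_params.spec,
                       start=params_to_vector(two_trait_params),
                       compute_information=False, maxiter=2)
        other = two_trait_spec(cross_degree=None)
        sp = _single_trait_spec("FI", {GENETIC: (0, 0), ENVIRONMENTAL: (0, 0)})
        d1 = build_design(pheno, FixedSpec(), cfg.grid, ("FI",), A)
        fit1 = fit_reml(d1, A, sp, compute_information=False, maxiter=2)
        with pytest.raises(ValueError):
            lrt(fit1, fit)


class TestBlup:
    def test_zero_genetic_variance_shrinks_to_zero(self):
        spec = _single_trait_spec("FI", {GENETIC: (0, 0), ENVIRONMENTAL: (0, 0)})
        from longsad import SadParams
        p = SadParams(spec,
                      theta={("FI", GENETIC): (0.0,), ("FI", ENVIRONMENTAL): (0.0,)},
                      logvar={("FI", GENETIC): (np.log(1e-8),),
                              ("FI", ENVIRONMENTAL): (0.0,)})
        cfg = default_config(n_generations=2, n_sires=2, n_dams=3, litter_size=2,
                             grid=TimeGrid.weeks(2), seed=1)
        cfg.params = p
        cfg.trait_means = {"FI": (0.0, 0.0)}
        ped, pheno, _ = simulate_dataset(cfg, complete=True)
        A = build_A(ped)
        data = build_design(pheno, FixedSpec(), cfg.grid, ("FI",), A)
        fit = fit_reml(data, A, spec, start=params_to_vector(p),
                       frozen=np.ones(4, bool), compute_information=False)
        bl = blup_solve(fit, A)
        assert np.max(np.abs(bl["tebv"])) < 1e-5

    def test_matches_mme_oracle(self, two_trait_params):
        """Toy pedigree: BLUP equals the dense mixed-model-equation solution."""
        cfg, ped, pheno, _ = toy_dataset(seed=11, weeks=2, params=two_trait_params)
        A = build_A(ped)
        spec = two_trait_params.spec
        data = build_design(pheno, FixedSpec(), cfg.grid, spec.traits, A)
        om = params_to_vector(two_trait_params)
        fit = fit_reml(data, A, spec, start=om, frozen=np.ones(len(om), bool),
                       compute_information=False)
        bl = blup_solve(fit, A)
        # dense MME: all pedigree animals in u, phenotyped ones in residual
        N, m = data.Y.shape
        Sg = multi_trait_covariance(two_trait_params, cfg.grid, GENETIC)
        Se = multi_trait_covariance(two_trait_params, cfg.grid, ENVIRONMENTAL)
        q = len(ped)
        pos = {a: i for i, a in enumerate(A.ids)}
        y = data.Y.ravel()
        X = data.X.reshape(N * m, -1)
        Z = np.zeros((N * m, q * m))
        for ai, a in enumerate(data.animals):
            j = pos[a]
            Z[ai * m:(ai + 1) * m, j * m:(j + 1) * m] = np.eye(m)
        R = np.kron(np.eye(N), Se)
        Ginv = np.kron(np.linalg.inv(A.values), np.linalg.inv(Sg))
        Rinv = np.linalg.inv(R)
        C = np.block([
            [X.T @ Rinv @ X, X.T @ Rinv @ Z],
            [Z.T @ Rinv @ X, Z.T @ Rinv @ Z + Ginv],
        ])
        rhs = np.concatenate([X.T @ Rinv @ y, Z.T @ Rinv @ y])
        sol = np.linalg.solve(C, rhs)
        u_mme = sol[X.shape[1]:].reshape(q, m)
        np.testing.assert_allclose(bl["tebv"], u_mme, atol=1e-6)

    def test_unphenotyped_offspring_is_parent_average(self, two_trait_params):
        """Offspring of two phenotyped parents, itself unphenotyped and
        childless: TEBV = mean of parental TEBV."""
        ped = build_A  # noqa: F841 (clarity)
        from longsad import Pedigree
        recs = [("s", "0", "0"), ("d", "0", "0"), ("kid", "s", "d")]
        ped = Pedigree(recs)
        A = build_A(ped)
        cfg = default_config(n_generations=1, n_sires=1, n_dams=1,
                             grid=TimeGrid.weeks(2), seed=2)
        cfg.params = two_trait_params
        cfg.trait_means = {"ADG": (0, 0), "FI": (0, 0)}
        eff = simulate_effects(ped, two_trait_params, cfg.grid, 3)
        pheno = assemble_phenotypes(eff, cfg, phenotyped=["s", "d"])
        spec = two_trait_params.spec
        data = build_design(pheno, FixedSpec(), cfg.grid, spec.traits, A)
        om = params_to_vector(two_trait_params)
        fit = fit_reml(data, A, spec, start=om, frozen=np.ones(len(om), bool),
                       compute_information=False)
        bl = blup_solve(fit, A)
        i = {a: k for k, a in enumerate(bl["ids"])}
        np.testing.assert_allclose(
            bl["tebv"][i["kid"]],
            0.5 * (bl["tebv"][i["s"]] + bl["tebv"][i["d"]]),
            atol=1e-8,
        )


class TestInformationConditionNumber:
    def test_known_matrices(self, two_trait_params):
        cfg, ped, pheno, _ = toy_dataset(seed=12, weeks=2, params=two_trait_params)
        A = build_A(ped)
        spec = two_trait_params.spec
        data = build_design(pheno, FixedSpec(), cfg.grid, spec.traits, A)
        fit = fit_reml(data, A, spec, start=params_to_vector(two_trait_params),
                       compute_information=False, maxiter=2)
        fit.information = np.eye(3)
        assert information_condition_number(fit)[0] == pytest.approx(1.0)
        fit.information = np.diag([4.0, 1.0])
        assert information_condition_number(fit)[0] == pytest.approx(2.0)
        rng = np.random.default_rng(1)
        M = rng.standard_normal((5, 5))
        spd = M @ M.T + 5 * np.eye(5)
        fit.information = spd
        lam = np.linalg.eigvalsh(spd)
        assert information_condition_number(fit)[0] == pytest.approx(
            np.sqrt(lam[-1] / lam[0]))
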