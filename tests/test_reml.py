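"""Animal-model REML/BLUP against dense generalized-least-squares and
closed-form oracles, plus likelihood-monotonicity and recovery properties."""

import numpy as np
import pandas as pd
import pytest

from marelife import (
    ModelSpec,
    SimulationConfig,
    VarianceComponents,
    build_A,
    build_D,
    build_mme,
    compute_kinship,
    heritability,
    reml_estimate,
    se_heritability,
    simulate_pedigree,
    simulate_phenotypes,
    solve_blup,
)

from conftest import SMALL_CFG, make_pedigree


def toy_population(rng, n_founders=6, n_mares=24):
    """Small two-generation pedigree with phenotyped daughters."""
    rows = [(i, 0, 0, 1990, "M" if i <= 2 else "F") for i in range(1, n_founders + 1)]
    nid = n_founders + 1
    for _ in range(n_mares):
        s = int(rng.integers(1, 3))
        d = int(rng.integers(3, n_founders + 1))
        rows.append((nid, s, d, 2000, "F"))
        nid += 1
    ped = make_pedigree(rows)
    mares = [r[0] for r in rows if r[3] == 2000]
    ph = pd.DataFrame(
        {
            "mare_id": mares,
            "value": rng.normal(0.7, 0.12, len(mares)),
            "af_class": rng.choice([3, 4], len(mares)),
            "F": 0.0,
            "eu_id": rng.integers(1, 4, len(mares)),
            "birth_year": 2000,
        }
    )
    return ped, ph


def dense_gls_blup(ph, ped, vc, model):
    """Independent oracle: GLS fixed effects and BLUP via dense V inverse."""
    A, ped_sorted = build_A(ped)
    idx = {a: i for i, a in enumerate(ped_sorted["animal_id"])}
    m = np.array([idx[x] for x in ph["mare_id"]])
    n = len(ph)
    X_cols = [np.ones(n)]
    if ph["af_class"].nunique() > 1:
        X_cols.append((ph["af_class"] == 4).astype(float).to_numpy())
    X = np.column_stack(X_cols)
    levels = sorted(set(zip(ph["eu_id"], ph["birth_year"])))
    lut = {lv: i for i, lv in enumerate(levels)}
    h = np.array([lut[x] for x in zip(ph["eu_id"], ph["birth_year"])])
    Zh = np.zeros((n, len(levels)))
    Zh[np.arange(n), h] = 1.0
    n_ped = len(ped_sorted)
    Za = np.zeros((n, n_ped))
    Za[np.arange(n), m] = 1.0
    D = build_D(ped_sorted, A)
    V = (
        vc.var_herd * Zh @ Zh.T
        + vc.var_additive * Za @ A @ Za.T
        + vc.var_dominance * D[np.ix_(m, m)]
        + vc.var_residual * np.eye(n)
    )
    Vinv = np.linalg.inv(V)
    y = ph["value"].to_numpy()
    beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    r = Vinv @ (y - X @ beta)
    ebv = vc.var_additive * (A @ Za.T) @ r
    herd = vc.var_herd * Zh.T @ r
    dom = vc.var_dominance * D[np.ix_(m, m)] @ r
    return beta, pd.Series(ebv, index=ped_sorted["animal_id"].to_numpy()), herd, dom, levels


class TestMmeAgainstDenseGls:
    def test_solutions_match_oracle(self, rng):
        ped, ph = toy_population(rng)
        vc = VarianceComponents(
            var_herd=0.002, var_additive=0.005, var_dominance=0.002, var_residual=0.010
        )
        model = ModelSpec(use_inbreeding=False)
        sol = solve_blup(ph, compute_kinship(ped), vc, model=model)
        beta, ebv, herd, dom, levels = dense_gls_blup(ph, ped, vc, model)
        np.testing.assert_allclose(sol["beta"], beta, atol=1e-8)
        np.testing.assert_allclose(
            sol["ebv"].loc[ebv.index].to_numpy(), ebv.to_numpy(), atol=1e-8
        )
        np.testing.assert_allclose(
            [sol["herd"][lv] for lv in levels], herd, atol=1e-8
        )
        np.testing.assert_allclose(
            sol["dominance"].loc[ph["mare_id"]].to_numpy(), dom, atol=1e-8
        )

    def test_mme_sparse_symmetric(self, rng):
        ped, ph = toy_population(rng)
        vc = VarianceComponents(0.002, 0.005, 0.002, 0.010)
        C, rhs, layout = build_mme(ph, compute_kinship(ped), vc)
        d = (C - C.T).toarray()
        assert np.abs(d).max() < 1e-10
        assert C.shape[0] == layout["n_equations"] == len(rhs)

    def test_huge_lambda_shrinks_random_effects_to_ols(self, rng):
        ped, ph = toy_population(rng)
        vc = VarianceComponents(1e-14, 1e-14, 1e-14, 0.01)
        model = ModelSpec(use_inbreeding=False)
        sol = solve_blup(ph, compute_kinship(ped), vc, model=model)
        assert np.abs(sol["ebv"]).max() < 1e-6
        X = np.column_stack(
            [np.ones(len(ph)), (ph["af_class"] == 4).astype(float)]
        )
        ols = np.linalg.lstsq(X, ph["value"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(sol["beta"], ols, atol=1e-5)

    def test_constant_phenotypes_give_zero_ebvs(self, rng):
        ped, ph = toy_population(rng)
        ph["value"] = 0.7
        ph["af_class"] = 3
        vc = VarianceComponents(0.001, 0.005, 0.001, 0.010)
        sol = solve_blup(ph, compute_kinship(ped), vc, model=ModelSpec(use_inbreeding=False))
        assert np.abs(sol["ebv"]).max() < 1e-10


class TestRemlOracles:
    def test_balanced_one_way_anova(self, rng):
        # founders-only mares in balanced herd groups; herd + residual model
        # has the closed-form ANOVA solution sigma_e = MSW,
        # sigma_h = (MSB - MSW) / m
        q, m = 12, 8
        rows = [(i, 0, 0, 1995, "F") for i in range(1, q * m + 1)]
        ped = make_pedigree(rows)
        herd_eff = rng.normal(0, 0.1, q)
        y = np.concatenate([0.7 + herd_eff[g] + rng.normal(0, 0.15, m) for g in range(q)])
        ph = pd.DataFrame(
            {
                "mare_id": np.arange(1, q * m + 1),
                "value": y,
                "af_class": 3,
                "F": 0.0,
                "eu_id": np.repeat(np.arange(1, q + 1), m),
                "birth_year": 1995,
            }
        )
        model = ModelSpec(include_additive=False, include_dominance=False,
                          use_af=False, use_inbreeding=False)
        vc = reml_estimate(ph, compute_kinship(ped), model=model, tol=1e-10)
        groups = y.reshape(q, m)
        msw = groups.var(axis=1, ddof=1).mean()
        msb = m * groups.mean(axis=1).var(ddof=1)
        np.testing.assert_allclose(vc.var_residual, msw, rtol=1e-5)
        np.testing.assert_allclose(vc.var_herd, (msb - msw) / m, rtol=1e-4)

    def test_zero_additive_variance_recovered_at_floor(self):
        h2s = []
        for seed in range(3):
            cfg = SimulationConfig(
                seed=seed, var_additive=0.0, var_dominance=0.0,
                var_herd=0.5e-3, var_residual=15e-3, **SMALL_CFG,
            )
            ped, truth = simulate_pedigree(cfg)
            ph = simulate_phenotypes(ped, truth, cfg).iloc[:400]
            km = compute_kinship(ped)
            vc = reml_estimate(ph, km, tol=1e-6, max_iter=40)
            h2s.append(vc.h2)
        assert np.mean(h2s) < 0.05

    def test_logL_monotone_every_iteration(self, small_phenotypes, small_kinship):
        vc = reml_estimate(
            small_phenotypes.iloc[:400], small_kinship, tol=1e-7, max_iter=40
        )
        steps = np.diff(vc.logL_history)
        assert (steps > -1e-6).all()
        assert vc.n_iterations >= 1 and len(vc.logL_history) == vc.n_iterations + 1

    def test_aic_definition(self, small_phenotypes, small_kinship):
        vc = reml_estimate(
            small_phenotypes.iloc[:300], small_kinship, tol=1e-6, max_iter=30
        )
        assert vc.aic == pytest.approx(-2 * vc.logL + 8)


class TestHeritability:
    def test_reference_component_ratio(self):
        vc = VarianceComponents(0.141e-3, 4.848e-3, 1.628e-3, 13.426e-3)
        assert heritability(vc) == pytest.approx(0.242, abs=5e-4)

    def test_zero_additive(self):
        vc = VarianceComponents(0.1, 0.0, 0.0, 0.9)
        assert vc.h2 == 0.0
        assert se_heritability(vc) == 0.0

    def test_zero_sampling_covariances_give_zero_se(self):
        vc = VarianceComponents(0.1, 0.3, 0.1, 0.5,
                                component_names=("herd", "additive", "dominance", "residual"))
        vc.cov_components = np.zeros((4, 4))
        assert se_heritability(vc) == 0.0

    def test_se_formula_delta_method(self):
        vc = VarianceComponents(0.0, 4.0, 0.0, 16.0,
                                component_names=("herd", "additive", "dominance", "residual"))
        cov = np.zeros((4, 4))
        cov[1, 1] = 0.25      # Var(sigma_a)
        cov[3, 3] = 1.0       # Var(sigma_e)
        vc.cov_components = cov
        sa, sp = 4.0, 20.0
        var_p = cov.sum()
        cov_ap = cov[1].sum()
        expected = (sa / sp) * np.sqrt(
            0.25 / sa**2 + var_p / sp**2 - 2 * cov_ap / (sa * sp)
        )
        assert se_heritability(vc) == pytest.approx(expected)

    def test_zero_phenotypic_variance_rejected(self):
        with pytest.raises(ValueError):
            heritability(VarianceComponents(0, 0, 0, 0))


class TestGeneticSignalRecovery:
    def test_ebv_correlates_with_true_bv_and_grows_with_signal(self):
        cors = {}
        for label, sa in (("low", 1e-3), ("high", 12e-3)):
            cc = []
            for seed in (21, 22):
                cfg = SimulationConfig(seed=seed, var_additive=sa, **SMALL_CFG)
                ped, truth = simulate_pedigree(cfg)
                ph = simulate_phenotypes(ped, truth, cfg).iloc[:500]
                km = compute_kinship(ped)
                vc = reml_estimate(ph, km, tol=1e-6, max_iter=30)
                sol = solve_blup(ph, km, vc)
                ebv = sol["ebv"].loc[ph["mare_id"]]
                true = truth.breeding_value.loc[ph["mare_id"]]
                cc.append(np.corrcoef(ebv, true)[0, 1])
            cors[label] = np.mean(cc)
        assert cors["high"] > cors["low"] > 0

    def test_dropping_dominance_does_not_deflate_h2(self, rng):
        # dominance deviations drawn with the D covariance, so the
        # no-dominance model pushes part of that variance into the
        # additive term (as seen when comparing nested animal models)
        diffs = []
        for seed in (31, 32, 33):
            cfg = SimulationConfig(seed=seed, var_dominance=6e-3, **SMALL_CFG)
            ped, truth = simulate_pedigree(cfg)
            ph = simulate_phenotypes(ped, truth, cfg).iloc[:500]
            km = compute_kinship(ped)
            D_m = km.subset_D(ph["mare_id"].to_numpy())
            # re-draw dominance with covariance D_m instead of iid
            L = np.linalg.cholesky(D_m + 1e-8 * np.eye(len(D_m)))
            rr = np.random.default_rng(seed)
            structured = L @ rr.standard_normal(len(D_m)) * np.sqrt(cfg.var_dominance)
            iid = truth.dominance_deviation.loc[ph["mare_id"]].to_numpy()
            ph = ph.copy()
            ph["value"] = ph["value"].to_numpy() - iid + structured
            full = reml_estimate(ph, km, D_m=D_m, tol=1e-6, max_iter=40)
            nodom = reml_estimate(
                ph, km, model=ModelSpec(include_dominance=False), tol=1e-6, max_iter=40
            )
            diffs.append(nodom.h2 - full.h2)
        assert np.mean(diffs) > -0.01
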