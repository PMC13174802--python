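"""Tests of the DWLS structural-model engine."""

import numpy as np
import pytest

import stratsem as st
from stratsem._linalg import vech_pairs, vech_position
from stratsem.exceptions import (
    CollinearityError,
    DegenerateContrastError,
    InvalidArgumentError,
)
from stratsem.sem import (
    Factor,
    ModelSpec,
    Regression,
    StructuralModel,
    equality_constrained_spec,
    factor_residual_model,
    fit_dwls,
    genetic_multiple_regression,
    residual_chisq,
    wald_equality_test,
)
from conftest import fixed_diag_vr


def corr3(rab, rax, rbx):
    r = np.eye(3)
    r[0, 1] = r[1, 0] = rab
    r[0, 2] = r[2, 0] = rax
    r[1, 2] = r[2, 1] = rbx
    return r


class TestFitDWLS:
    def test_saturated_bivariate_model(self):
        R = np.array([[1.0, 0.37], [0.37, 1.0]])
        fit = fit_dwls(ModelSpec(variables=("a", "b"), correlations=(("a", "b"),)),
                       R, fixed_diag_vr(2))
        assert fit.df == 0
        assert fit.fitval == pytest.approx(0.0, abs=1e-12)
        assert fit["r(a,b)"] == pytest.approx(0.37, abs=1e-10)
        assert fit.chisq == 0.0 and fit.p == 1.0

    def test_equal_weight_constrained_average(self):
        R = corr3(0.5, 0.2, 0.4)
        spec = equality_constrained_spec("a", "b", "x", ("a", "b", "x"))
        fit = fit_dwls(spec, R, fixed_diag_vr(3))
        assert fit.df == 1
        assert fit["r(a,x)"] == pytest.approx(0.3, abs=1e-8)
        assert fit["r(a,b)"] == pytest.approx(0.5, abs=1e-8)

    def test_triad_closed_form_loadings(self):
        R = corr3(0.56, 0.42, 0.48)
        spec = ModelSpec(variables=("i1", "i2", "i3"),
                         factors=(Factor("F", ("i1", "i2", "i3")),))
        fit = fit_dwls(spec, R, fixed_diag_vr(3))
        lam1 = np.sqrt(0.56 * 0.42 / 0.48)
        lam2 = np.sqrt(0.56 * 0.48 / 0.42)
        lam3 = np.sqrt(0.42 * 0.48 / 0.56)
        assert fit["l(F,i1)"] == pytest.approx(lam1, abs=1e-6)
        assert fit["l(F,i2)"] == pytest.approx(lam2, abs=1e-6)
        assert fit["l(F,i3)"] == pytest.approx(lam3, abs=1e-6)
        assert fit.df == 0

    def test_first_loading_sign_convention(self):
        R = corr3(0.56, 0.42, 0.48)
        spec = ModelSpec(variables=("i1", "i2", "i3"),
                         factors=(Factor("F", ("i1", "i2", "i3")),))
        for seed in range(3):
            fit = fit_dwls(spec, R, fixed_diag_vr(3), seed=seed)
            assert fit["l(F,i1)"] > 0

    def test_heywood_case_flagged(self):
        R = corr3(0.9, 0.9, 0.5)  # triad solution exceeds 1
        spec = ModelSpec(variables=("i1", "i2", "i3"),
                         factors=(Factor("F", ("i1", "i2", "i3")),))
        fit = fit_dwls(spec, R, fixed_diag_vr(3))
        assert "heywood" in fit.flags or "inadmissible" in fit.flags

    def test_df_accounting_across_specs(self):
        specs = [
            ModelSpec(variables=("a", "b"), correlations=(("a", "b"),)),
            equality_constrained_spec("a", "b", "x", ("a", "b", "x")),
            ModelSpec(variables=("i1", "i2", "i3"),
                      factors=(Factor("F", ("i1", "i2", "i3")),)),
            ModelSpec(variables=("i1", "i2", "i3", "t1", "t2"),
                      factors=(Factor("F", ("i1", "i2", "i3")),),
                      factor_regressions=(("F", "t1"), ("F", "t2")),
                      residual_covariances=(("t1", "t2"),)),
            ModelSpec(variables=("y", "x1", "x2"),
                      regressions=(Regression("y", ("x1", "x2")),)),
        ]
        for spec in specs:
            k = len(spec.variables)
            model = StructuralModel(spec, np.eye(k) * 1.0, fixed_diag_vr(k))
            assert model.n_free() + model.df == k * (k - 1) // 2

    def test_nested_model_monotonicity(self, trio_corr):
        free = ModelSpec(variables=tuple(trio_corr.names),
                         correlations=(("a", "b"), ("a", "x"), ("b", "x")))
        constrained = equality_constrained_spec("a", "b", "x", trio_corr.names)
        f_free = fit_dwls(free, trio_corr.S, trio_corr.V)
        f_con = fit_dwls(constrained, trio_corr.S, trio_corr.V)
        assert f_con.fitval >= f_free.fitval - 1e-12

    def test_permutation_invariance(self, trio_corr):
        names = list(trio_corr.names)
        perm_names = [names[2], names[0], names[1]]
        sub = trio_corr.subset(perm_names)
        fit1 = fit_dwls(equality_constrained_spec("a", "b", "x", names),
                        trio_corr.S, trio_corr.V)
        fit2 = fit_dwls(equality_constrained_spec("a", "b", "x", perm_names),
                        sub.S, sub.V)
        assert fit1.chisq == pytest.approx(fit2.chisq, rel=1e-6)
        assert fit1.fitval == pytest.approx(fit2.fitval, rel=1e-6)
        assert fit1["r(a,x)"] == pytest.approx(fit2["r(a,x)"], abs=1e-8)

    def test_too_many_parameters_rejected(self):
        spec = ModelSpec(variables=("a", "b"), correlations=(("a", "b"),),
                         residual_covariances=(("a", "b"),))
        with pytest.raises(InvalidArgumentError):
            StructuralModel(spec, np.eye(2), fixed_diag_vr(2))


class TestResidualChisq:
    def test_saturated_returns_null(self):
        R = np.array([[1.0, 0.2], [0.2, 1.0]])
        fit = fit_dwls(ModelSpec(variables=("a", "b"), correlations=(("a", "b"),)),
                       R, fixed_diag_vr(2))
        assert residual_chisq(fit, fixed_diag_vr(2)) == (0.0, 0, 1.0)

    def test_agrees_with_wald_on_single_constraint(self, trio_corr):
        spec = equality_constrained_spec("a", "b", "x", trio_corr.names)
        fit = fit_dwls(spec, trio_corr.S, trio_corr.V)
        chisq, df, p = residual_chisq(fit, trio_corr.V)
        wald, _, _ = wald_equality_test(trio_corr.S, trio_corr.V,
                                        ("a", "x"), ("b", "x"),
                                        names=trio_corr.names)
        assert df == 1
        assert abs(chisq - wald) <= 0.10 * max(wald, 1e-6)


class TestWald:
    def test_null_contrast(self):
        R = corr3(0.5, 0.3, 0.3)
        chisq, df, p = wald_equality_test(R, fixed_diag_vr(3), (0, 2), (1, 2))
        assert chisq == 0.0 and df == 1 and p == 1.0

    def test_anorexia_style_contrast_arithmetic(self):
        # (0.38 - 0.12)^2 / (0.01 + 0.01) = 3.38
        k = 3
        R = corr3(0.5, 0.38, 0.12)
        V = fixed_diag_vr(3, var=0.01)
        chisq, df, p = wald_equality_test(R, V, (0, 2), (1, 2))
        assert chisq == pytest.approx(3.38, rel=1e-12)

    def test_scale_invariance(self):
        R1 = corr3(0.5, 0.2, 0.4)
        R2 = corr3(0.5, 0.4, 0.8)
        c1, _, _ = wald_equality_test(R1, fixed_diag_vr(3, 0.01), (0, 2), (1, 2))
        c2, _, _ = wald_equality_test(R2, fixed_diag_vr(3, 0.04), (0, 2), (1, 2))
        assert c1 == pytest.approx(c2, rel=1e-12)

    def test_degenerate_variance_rejected(self):
        R = corr3(0.5, 0.2, 0.4)
        V = np.zeros((6, 6))
        with pytest.raises(DegenerateContrastError):
            wald_equality_test(R, V, (0, 2), (1, 2))


class TestMultipleRegression:
    def test_orthogonal_predictors_give_marginal_betas(self):
        R = np.eye(3)
        names = ("y", "x1", "x2")
        R[1, 0] = R[0, 1] = 0.3   # r(x1, y)
        R[2, 0] = R[0, 2] = 0.4   # r(x2, y)
        res = genetic_multiple_regression(R, fixed_diag_vr(3), "y",
                                          ("x1", "x2"), names=names)
        np.testing.assert_allclose(res.betas, [0.3, 0.4], atol=1e-12)

    def test_correlated_predictors_match_direct_solve(self):
        names = ("y", "x1", "x2")
        R = np.eye(3)
        R[1, 2] = R[2, 1] = 0.5
        R[0, 1] = R[1, 0] = 0.3
        R[0, 2] = R[2, 0] = 0.4
        res = genetic_multiple_regression(R, fixed_diag_vr(3), "y",
                                          ("x1", "x2"), names=names)
        direct = np.linalg.solve(np.array([[1.0, 0.5], [0.5, 1.0]]),
                                 np.array([0.3, 0.4]))
        np.testing.assert_allclose(res.betas, direct, atol=1e-10)
        assert res.predictor_correlation == pytest.approx(0.5)

    def test_collinearity_guard_names_pair(self):
        names = ("y", "late", "male")
        R = np.eye(3)
        R[1, 2] = R[2, 1] = 0.99
        with pytest.raises(CollinearityError) as err:
            genetic_multiple_regression(R, fixed_diag_vr(3), "y",
                                        ("late", "male"), names=names)
        assert err.value.pair == ("late", "male")

    def test_delta_method_ses_track_input_variance(self):
        names = ("y", "x1", "x2")
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 0.3
        res_small = genetic_multiple_regression(R, fixed_diag_vr(3, 1e-6), "y",
                                                ("x1", "x2"), names=names)
        res_big = genetic_multiple_regression(R, fixed_diag_vr(3, 1e-2), "y",
                                              ("x1", "x2"), names=names)
        assert np.all(res_big.ses > res_small.ses)
        np.testing.assert_allclose(res_big.ses, 100 * res_small.ses, rtol=1e-6)


class TestFactorResidualModel:
    def _vr(self, k, var=1e-4):
        return fixed_diag_vr(k, var)

    def test_targets_unrelated_to_factor_keep_raw_association(self):
        # indicators correlate via the factor; targets only with each other
        lam = np.array([0.7, 0.8, 0.6])
        k = 5
        R = np.eye(k)
        R[:3, :3] = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        R[3, 4] = R[4, 3] = 0.25
        names = ["i1", "i2", "i3", "t1", "t2"]
        fr = factor_residual_model(R, self._vr(k), ["i1", "i2", "i3"],
                                   ["t1", "t2"], names)
        assert abs(fr.paths["t1"]) < 1e-6
        assert abs(fr.paths["t2"]) < 1e-6
        assert fr.adjusted[("t1", "t2")] == pytest.approx(0.25, abs=1e-6)

    def test_fully_mediated_association_vanishes(self):
        load = np.array([0.7, 0.8, 0.6, 0.57, 0.13])
        R = np.outer(load, load)
        np.fill_diagonal(R, 1.0)
        names = ["i1", "i2", "i3", "late", "early"]
        fr = factor_residual_model(R, self._vr(5), ["i1", "i2", "i3"],
                                   ["late", "early"], names)
        assert fr.paths["late"] == pytest.approx(0.57, abs=1e-6)
        assert fr.paths["early"] == pytest.approx(0.13, abs=1e-6)
        assert abs(fr.adjusted[("late", "early")]) < 1e-6

    def test_path_recovery_under_simulation(self):
        # generative recovery of factor->target paths (0.57, 0.13)
        load = np.array([0.7, 0.8, 0.6, 0.57, 0.13])
        names = ["i1", "i2", "i3", "late", "early"]
        Rg = np.outer(load, load)
        np.fill_diagonal(Rg, 1.0)
        traits = [st.SimTraitSpec(n, "continuous", h2=0.25, n_total=20000)
                  for n in names]
        paths_late, paths_early, resid = [], [], []
        for s in range(25):
            cfg = st.SimBatteryConfig(traits=traits, Rg=Rg, M=2000, seed=500 + s)
            tables, ld, _ = st.simulate_battery(cfg)
            g = st.multivariable_ldsc(tables, ld, cfg.trait_metas(),
                                      n_blocks=100).standardize()
            fr = factor_residual_model(g.S, g.V, ["i1", "i2", "i3"],
                                       ["late", "early"], g.names, seed=s)
            paths_late.append(fr.paths["late"])
            paths_early.append(fr.paths["early"])
            resid.append(fr.adjusted[("late", "early")])
        for vals, truth in ((paths_late, 0.57), (paths_early, 0.13), (resid, 0.0)):
            vals = np.asarray(vals)
            mc_se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - truth) < 3 * mc_se

    def test_preconditions(self):
        R = np.eye(4)
        with pytest.raises(InvalidArgumentError):
            factor_residual_model(R, self._vr(4), ["a", "b"], ["c"],
                                  ["a", "b", "c", "d"])
        with pytest.raises(InvalidArgumentError):
            factor_residual_model(R, self._vr(4), ["a", "b", "c"], ["a"],
                                  ["a", "b", "c", "d"])
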