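"""Tests of the LD-score regression engine and jackknife machinery."""

import numpy as np
import pandas as pd
import pytest

import stratsem as st
from stratsem._linalg import is_psd, jackknife_cov, unvech, vech
from stratsem.exceptions import (
    InsufficientOverlapError,
    InvalidArgumentError,
    RankDeficiencyError,
    TraitError,
)
from stratsem.ldsc import ldsc_regression
from stratsem.simulate import LDShape, draw_z_scores


def blocks_for(m, b=20):
    return (np.arange(m) * b // m).astype(int)


class TestRegression:
    def test_noiseless_line_recovered_exactly(self):
        rng = np.random.default_rng(0)
        ell = LDShape(mean=40.0).draw(100, rng)
        y = 1.0 + 1000 * 0.5 * ell / 100
        fit = ldsc_regression(y, ell, 1000, 100, blocks_for(100))
        assert fit.slope == pytest.approx(0.5, abs=1e-10)
        assert fit.intercept == pytest.approx(1.0, abs=1e-8)

    def test_flat_response_gives_zero_slope(self):
        rng = np.random.default_rng(1)
        ell = LDShape(mean=40.0).draw(200, rng)
        fit = ldsc_regression(np.ones(200), ell, 1000, 200, blocks_for(200))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)

    def test_fixed_intercept(self):
        rng = np.random.default_rng(2)
        ell = LDShape(mean=40.0).draw(100, rng)
        y = 1.0 + 2000 * 0.3 * ell / 100
        fit = ldsc_regression(y, ell, 2000, 100, blocks_for(100), fix_intercept=1.0)
        assert fit.slope == pytest.approx(0.3, abs=1e-10)
        assert fit.intercept == 1.0

    def test_monte_carlo_recovery(self):
        # unbiasedness of the slope under the generative model
        rng_ld = np.random.default_rng(5)
        ell = LDShape(mean=40.0).draw(2000, rng_ld)
        est = []
        for rep in range(20):
            z = draw_z_scores(ell, np.array([[0.4]]), np.array([2000.0]),
                              np.eye(1), 2000, np.random.default_rng(100 + rep))
            fit = ldsc_regression(z[:, 0] ** 2, ell, 2000.0, 2000,
                                  blocks_for(2000, 200))
            est.append(fit.slope)
        est = np.asarray(est)
        mc_se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 0.4) < 3 * mc_se

    def test_constant_ell_rejected(self):
        with pytest.raises(RankDeficiencyError):
            ldsc_regression(np.ones(50), np.ones(50), 100, 50, blocks_for(50))

    def test_too_few_blocks_rejected(self):
        ell = np.linspace(1, 10, 50)
        with pytest.raises(InvalidArgumentError):
            ldsc_regression(np.ones(50), ell, 100, 50, np.zeros(50, dtype=int))


class TestJackknife:
    def test_delete_one_variance_of_mean_matches_classical_formula(self):
        # exact algebraic identity on equal-size blocks
        rng = np.random.default_rng(7)
        b, size = 25, 8
        data = rng.normal(size=b * size)
        total = data.sum()
        loo = np.array([(total - data[i * size:(i + 1) * size].sum())
                        / (len(data) - size) for i in range(b)])
        jack_var = jackknife_cov(loo[:, None])[0, 0]
        block_means = data.reshape(b, size).mean(axis=1)
        classical = block_means.var(ddof=1) / b
        assert jack_var == pytest.approx(classical, rel=1e-12)

    def test_constant_replicates_give_zero_covariance(self):
        loo = np.ones((30, 6)) * 3.14
        assert np.allclose(jackknife_cov(loo), 0.0)


class TestLiability:
    def test_half_prevalence_factor_is_half_pi(self):
        assert st.liability_factor(0.5, 0.5) == pytest.approx(np.pi / 2, abs=1e-9)

    def test_continuous_identity(self):
        assert st.liability_conversion(0.37) == pytest.approx(0.37)

    def test_mixed_pair_uses_sqrt_of_binary_factor(self):
        p = st.LiabilityParams(0.1, 0.5)
        c = st.liability_factor(0.1, 0.5)
        assert st.liability_conversion(1.0, p, None) == pytest.approx(np.sqrt(c))
        assert st.liability_conversion(1.0, p, p) == pytest.approx(c)

    @pytest.mark.parametrize("K", [0.0, 1.0, -0.1])
    def test_degenerate_prevalence_rejected(self, K):
        with pytest.raises(InvalidArgumentError):
            st.liability_factor(K, 0.5)


class TestMultivariable:
    def test_identical_tables_give_unit_genetic_correlation(self, trio_config):
        tables, ld, _ = st.simulate_battery(trio_config)
        specs = trio_config.trait_metas()[:2]
        gc = st.multivariable_ldsc([tables[0], tables[0].copy()], ld,
                                   specs, n_blocks=100)
        assert gc.S[0, 1] == pytest.approx(gc.S[0, 0], rel=1e-10)
        assert gc.standardize().S[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_sampling_covariance_is_psd(self, trio_gc):
        assert is_psd(trio_gc.V)
        assert is_psd(trio_gc.standardize().V)

    def test_point_estimates_near_truth(self, trio_config, trio_battery, trio_corr):
        _, _, truth = trio_battery
        for i in range(3):
            for j in range(i):
                est = trio_corr.S[i, j]
                se = np.sqrt(trio_corr.V[trio_corr.pair_position(
                    trio_corr.names[i], trio_corr.names[j])][
                        trio_corr.pair_position(trio_corr.names[i], trio_corr.names[j])])
                assert abs(est - truth.Rg[i, j]) < 5 * max(se, 0.01)

    def test_allele_flip_invariance_through_pipeline(self, trio_config):
        tables, ld, _ = st.simulate_battery(trio_config)
        registry = st.registry_from_battery(tables[0], ld)
        flipped = tables[1].copy()
        flipped["A1"], flipped["A2"] = tables[1]["A2"], tables[1]["A1"]
        flipped["Z"] = -tables[1]["Z"]
        specs = trio_config.trait_metas()
        munged_a = [st.munge(t, registry)[0] for t in tables]
        munged_b = [st.munge(t, registry)[0]
                    for t in [tables[0], flipped, tables[2]]]
        gc_a = st.multivariable_ldsc(munged_a, ld, specs, n_blocks=50)
        gc_b = st.multivariable_ldsc(munged_b, ld, specs, n_blocks=50)
        np.testing.assert_allclose(gc_a.S, gc_b.S, atol=1e-12)

    def test_insufficient_overlap_rejected(self, trio_config):
        tables, ld, _ = st.simulate_battery(trio_config)
        small = [t.head(50) for t in tables]
        with pytest.raises(InsufficientOverlapError):
            st.multivariable_ldsc(small, ld, trio_config.trait_metas())

    def test_liability_scale_flagged_and_converted(self):
        traits = [
            st.SimTraitSpec("bin", "binary", h2=0.2, K=0.05,
                            n_cases=5000, n_controls=5000),
            st.SimTraitSpec("cont", "continuous", h2=0.3, n_total=10000),
        ]
        cfg = st.SimBatteryConfig(traits=traits, Rg=np.eye(2), M=2000, seed=5)
        tables, ld, truth = st.simulate_battery(cfg)
        gc = st.multivariable_ldsc(tables, ld, cfg.trait_metas(), n_blocks=100)
        assert gc.scale == ["liability", "observed"]
        # liability h2 should be recovered, not the observed-scale value
        se = np.sqrt(gc.V[0, 0])
        assert abs(gc.S[0, 0] - 0.2) < 4 * se

    def test_save_load_round_trip(self, tmp_path, trio_gc):
        trio_gc.save(str(tmp_path / "gc"))
        back = st.GeneticCovariance.load(str(tmp_path / "gc"))
        np.testing.assert_allclose(back.S, trio_gc.S)
        np.testing.assert_allclose(back.V, trio_gc.V)
        np.testing.assert_allclose(back.replicates, trio_gc.replicates)
        assert back.names == trio_gc.names
        assert back.scale == trio_gc.scale

    def test_subset_preserves_values_and_dependencies(self, trio_corr):
        sub = trio_corr.subset(["a", "x"])
        assert sub.value("a", "x") == pytest.approx(trio_corr.value("a", "x"))
        p_full = trio_corr.pair_position("a", "x")
        p_sub = sub.pair_position("a", "x")
        assert sub.V[p_sub, p_sub] == pytest.approx(trio_corr.V[p_full, p_full])


class TestStandardize:
    def _manual_gc(self, S, reps):
        k = S.shape[0]
        return st.GeneticCovariance(
            names=[f"t{i}" for i in range(k)], S=S,
            V=jackknife_cov(reps), intercepts=np.eye(k), M=1000,
            h2_z=np.full(k, 10.0), replicates=reps,
            scale=["observed"] * k)

    def test_definition(self):
        S = np.array([[4.0, 1.0], [1.0, 1.0]])
        reps = np.tile(vech(S), (10, 1))
        g = self._manual_gc(S, reps).standardize()
        assert g.S[0, 1] == pytest.approx(0.5)
        assert np.allclose(np.diag(g.S), 1.0)

    def test_idempotent_on_correlation_input(self, trio_corr):
        again = trio_corr.standardize()
        np.testing.assert_allclose(again.S, trio_corr.S)
        np.testing.assert_allclose(again.V, trio_corr.V)

    def test_constant_replicates_give_zero_vr(self):
        S = np.array([[2.0, 0.4], [0.4, 1.0]])
        reps = np.tile(vech(S), (10, 1))
        g = self._manual_gc(S, reps).standardize()
        assert np.allclose(g.V, 0.0)

    def test_nonpositive_heritability_names_trait(self):
        S = np.array([[-0.1, 0.0], [0.0, 1.0]])
        reps = np.tile(vech(S), (10, 1))
        with pytest.raises(TraitError) as err:
            self._manual_gc(S, reps).standardize()
        assert err.value.trait == "t0"

    def test_se_calibration_against_monte_carlo(self):
        # empirical SD of the standardized estimate vs mean jackknife SE
        traits = [st.SimTraitSpec("a", "continuous", h2=0.25, n_total=8000),
                  st.SimTraitSpec("b", "continuous", h2=0.25, n_total=8000)]
        Rg = np.array([[1.0, 0.0], [0.0, 1.0]])
        est, ses = [], []
        for s in range(100):
            cfg = st.SimBatteryConfig(traits=traits, Rg=Rg, M=1000, seed=2000 + s)
            tables, ld, _ = st.simulate_battery(cfg)
            g = st.multivariable_ldsc(tables, ld, cfg.trait_metas(),
                                      n_blocks=100).standardize()
            est.append(g.value("a", "b"))
            ses.append(g.se("a", "b"))
        emp_sd = np.std(est, ddof=1)
        mean_se = np.mean(ses)
        assert abs(mean_se - emp_sd) / emp_sd < 0.25
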