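import numpy as np
import pandas as pd
import pytest

from volatempo import (RMASCA, LongitudinalModelSpec, asca_benchmark,
                       build_design, effect_matrices, fit_lmm, rank_loadings,
                       sca_decompose, scale_matrix)
from volatempo.utils import rng_stream, tucker_congruence


def _meta(groups=("FM", "I", "O"), times=(0, 4, 8, 12, 16, 20, 24), reps=3):
    rows = []
    for g in groups:
        for r in range(1, reps + 1):
            for t in times:
                rows.append({"sample_id": f"{g}-R{r}-{t}h", "group": g,
                             "replicate": r, "time_h": float(t)})
    return pd.DataFrame(rows)


class TestBuildDesign:
    def test_column_count_for_three_groups_seven_times(self):
        design = build_design(_meta(), LongitudinalModelSpec(0.0, "FM"))
        # intercept + 6 time dummies + 6*2 interaction dummies
        assert design.X.shape[1] == 19
        assert len(design.time_columns) == 6
        assert len(design.interaction_columns) == 12
        assert np.linalg.matrix_rank(design.X.to_numpy()) == 19

    def test_baseline_and_reference_have_no_interaction_columns(self):
        design = build_design(_meta(), LongitudinalModelSpec(0.0, "FM"))
        assert not any("time[0]" in c for c in design.interaction_columns)
        assert not any("group[FM]" in c for c in design.interaction_columns)

    def test_single_group_reduces_to_time_only(self):
        design = build_design(_meta(groups=("I",)),
                              LongitudinalModelSpec(0.0, "I"))
        assert design.interaction_columns == []
        assert design.X.shape[1] == 7

    def test_vessel_in_two_groups_rejected(self):
        meta = _meta(groups=("A", "B"), times=(0, 4, 8), reps=2)
        meta["vessel"] = "shared"
        with pytest.raises(ValueError, match="more than one group"):
            build_design(meta, LongitudinalModelSpec(0.0, "A"))

    def test_unknown_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            build_design(_meta(), LongitudinalModelSpec(2.0, "FM"))

    def test_rows_of_z_sum_to_one(self):
        design = build_design(_meta(), LongitudinalModelSpec(0.0, "FM"))
        np.testing.assert_array_equal(design.Z.sum(axis=1).to_numpy(), 1.0)


class TestFitLmm:
    def test_noiseless_response_recovered_exactly(self):
        design = build_design(_meta(), LongitudinalModelSpec(0.0, "FM"))
        rng = rng_stream(0, "lmm-test")
        beta = rng.normal(size=design.X.shape[1])
        y = design.X.to_numpy() @ beta
        fit = fit_lmm(y, design)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-8)
        assert fit.re_var == 0.0 and fit.resid_var == 0.0
        assert "exact-fit" in fit.flags

    def test_balanced_time_only_fixed_effects_equal_ols(self):
        # Zyskind-closed design: a complete balanced single-group (time-only)
        # model, where GLS at any vessel variance collapses to OLS
        design = build_design(_meta(groups=("I",), reps=8),
                              LongitudinalModelSpec(0.0, "I"))
        rng = rng_stream(1, "lmm-test")
        X = design.X.to_numpy()
        vessels = design.vessel_labels.astype("category").cat.codes.to_numpy()
        u = rng.normal(0, 1.0, vessels.max() + 1)
        y = X @ rng.normal(size=X.shape[1]) + u[vessels] + rng.normal(0, 1, len(X))
        fit = fit_lmm(y, design)
        assert fit.re_var > 0  # the equality is not the trivial tau=0 case
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.max(np.abs(fit.params.to_numpy() - ols)) < 1e-8

    def test_baseline_constrained_multigroup_gls_reweights(self):
        # with the group main effect removed, the group indicator leaves the
        # fixed-effect column space, so GLS at a positive vessel variance is
        # a genuinely different (more efficient) estimator than OLS
        design = build_design(_meta(), LongitudinalModelSpec(0.0, "FM"))
        rng = rng_stream(2, "lmm-test")
        X = design.X.to_numpy()
        Z = design.Z.to_numpy()
        y = (X @ rng.normal(size=X.shape[1]) + Z @ rng.normal(0, 1.0, Z.shape[1])
             + rng.normal(0, 1, len(X)))
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        tau2 = 1.0
        Vi = np.linalg.inv(np.eye(len(X)) + tau2 * Z @ Z.T)
        gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        assert np.max(np.abs(gls - ols)) > 1e-3

    def test_variance_components_recovered_with_many_vessels(self):
        rows = []
        for v in range(200):
            g = "A" if v % 2 else "B"
            for t in (0.0, 4.0, 8.0):
                rows.append({"group": g, "replicate": v, "time_h": t})
        design = build_design(pd.DataFrame(rows),
                              LongitudinalModelSpec(0.0, "A"))
        rng = rng_stream(7, "vc-test")
        u = rng.normal(0, 1, 200)
        y = u[design.meta["replicate"].to_numpy()] + rng.normal(
            0, 1, len(design.meta)
        )
        fit = fit_lmm(y, design)
        assert fit.converged
        assert fit.re_var == pytest.approx(1.0, rel=0.2)
        assert fit.resid_var == pytest.approx(1.0, rel=0.2)

    def test_non_finite_response_rejected(self):
        design = build_design(_meta(), LongitudinalModelSpec(0.0, "FM"))
        y = np.zeros(len(design.X))
        y[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_lmm(y, design)


class TestEffectMatrices:
    @pytest.fixture()
    def design(self):
        return build_design(_meta(), LongitudinalModelSpec(0.0, "FM"))

    def test_zero_time_coefficients_give_zero_time_matrix(self, design):
        coef = pd.DataFrame(0.0, index=design.X.columns, columns=["v1", "v2"])
        coef.loc[design.interaction_columns, "v1"] = 1.0
        dec = effect_matrices(coef, design)
        assert not dec.M_time.to_numpy().any()
        assert dec.M_interaction.to_numpy().any()

    def test_combined_is_entrywise_sum(self, design):
        rng = rng_stream(3, "effects-test")
        coef = pd.DataFrame(rng.normal(size=(design.X.shape[1], 4)),
                            index=design.X.columns,
                            columns=[f"v{i}" for i in range(4)])
        dec = effect_matrices(coef, design)
        np.testing.assert_allclose(
            dec.M_combined.to_numpy(),
            dec.M_time.to_numpy() + dec.M_interaction.to_numpy(),
        )

    def test_baseline_rows_have_zero_interaction(self, design):
        rng = rng_stream(4, "effects-test")
        coef = pd.DataFrame(rng.normal(size=(design.X.shape[1], 2)),
                            index=design.X.columns, columns=["a", "b"])
        dec = effect_matrices(coef, design)
        baseline = design.meta["time_h"] == 0.0
        assert not dec.M_interaction.loc[baseline.to_numpy()].to_numpy().any()

    def test_missing_coefficients_rejected(self, design):
        coef = pd.DataFrame(0.0, index=design.X.columns[:-1], columns=["v"])
        with pytest.raises(ValueError, match="missing"):
            effect_matrices(coef, design)


class TestScaDecompose:
    def test_rank_one_matrix_explained_fully_by_pc1(self):
        rng = rng_stream(5, "sca-test")
        M = pd.DataFrame(np.outer(rng.normal(size=20), rng.normal(size=6)),
                         columns=[f"v{i}" for i in range(6)])
        sca = sca_decompose(M, n_components=1)
        assert sca.explained_pct[0] == pytest.approx(100.0)
        np.testing.assert_allclose(
            np.linalg.norm(sca.loadings.to_numpy(), axis=0), 1.0, rtol=1e-10
        )

    def test_zero_matrix_flagged_no_effect(self):
        M = pd.DataFrame(np.zeros((5, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="no effect"):
            sca_decompose(M)

    def test_requesting_beyond_rank_truncates_with_warning(self):
        rng = rng_stream(6, "sca-test")
        M = pd.DataFrame(np.outer(rng.normal(size=10), rng.normal(size=4)),
                         columns=list("abcd"))
        with pytest.warns(UserWarning, match="rank"):
            sca = sca_decompose(M, n_components=3)
        assert sca.n_components == 1

    def test_sign_convention_largest_loading_positive(self):
        rng = rng_stream(7, "sca-test")
        M = pd.DataFrame(rng.normal(size=(15, 5)), columns=list("abcde"))
        sca = sca_decompose(M, n_components=3)
        for comp in sca.loadings.columns:
            col = sca.loadings[comp].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_explained_variances_sum_to_total_over_full_rank(self):
        rng = rng_stream(8, "sca-test")
        M = pd.DataFrame(rng.normal(size=(12, 5)), columns=list("abcde"))
        sca = sca_decompose(M)
        assert sca.explained_pct.sum() == pytest.approx(100.0)
        assert np.all(np.diff(sca.explained_pct) <= 1e-12)


class TestRecoveryAndValidation:
    def test_pc1_loadings_recover_generating_contrast(self, benchmark_fit):
        _table, truth, fit = benchmark_fit
        pc1 = fit.sca_for("combined").loadings["PC1"].to_numpy()
        assert abs(tucker_congruence(pc1, truth["contrast"])) >= 0.95

    def test_informative_variables_dominate_loading_ranking(self, benchmark_fit):
        _table, truth, fit = benchmark_fit
        ranked = fit.rank_loadings(component=1, k=10)
        top = set(ranked.loc[ranked["direction"] == "top", "variable"])
        informative = set(np.array(truth["variables"])[truth["informative"]])
        assert len(top & informative) >= 9

    def test_identical_replicates_give_zero_width_envelopes(self):
        table, _ = asca_benchmark(residual_sd=0.0, vessel_sd=0.0, seed=0)
        with pytest.warns(UserWarning, match="rank"):
            # noiseless effect matrices are rank 1; truncation is expected
            fit = RMASCA(scale_matrix(table, method="none"),
                         n_components=2).fit(engine="ols")
        env = fit.bootstrap(n_resamples=50, seed=0)
        # resamples are bitwise identical; residual widths only reflect the
        # two numerical routes (lstsq point fit vs normal-equation refits)
        widths = env.score_ci["upper"] - env.score_ci["lower"]
        assert np.max(widths) < 1e-7 * env.score_ci["point"].abs().max()
        lwidths = env.loading_ci["upper"] - env.loading_ci["lower"]
        assert np.max(lwidths) < 1e-7

    def test_bootstrap_seed_determinism(self, benchmark_fit):
        _table, _truth, fit = benchmark_fit
        a = fit.bootstrap(n_resamples=50, seed=5)
        b = fit.bootstrap(n_resamples=50, seed=5)
        pd.testing.assert_frame_equal(a.score_ci, b.score_ci)
        pd.testing.assert_frame_equal(a.loading_ci, b.loading_ci)

    def test_envelopes_contain_point_estimates(self, benchmark_fit):
        _table, _truth, fit = benchmark_fit
        env = fit.bootstrap(n_resamples=100, seed=1)
        assert (env.score_ci["lower"] <= env.score_ci["point"]).all()
        assert (env.score_ci["point"] <= env.score_ci["upper"]).all()
        assert (env.loading_ci["lower"] <= env.loading_ci["point"]).all()

    def test_jackknife_produces_one_resample_per_vessel(self, benchmark_fit):
        _table, _truth, fit = benchmark_fit
        env = fit.bootstrap(method="jackknife", seed=0)
        assert env.n_resamples == 9

    def test_single_vessel_group_rejected(self):
        table, _ = asca_benchmark(replicates=1, seed=0)
        fit = RMASCA(scale_matrix(table, method="none"), n_components=2).fit(
            engine="ols"
        )
        with pytest.raises(ValueError, match="fewer than 2 vessels"):
            fit.bootstrap(n_resamples=10, seed=0)

    def test_summary_mentions_explained_variance(self, benchmark_fit):
        _table, _truth, fit = benchmark_fit
        text = fit.summary()
        assert "combined" in text and "PC1" in text


class TestRankLoadings:
    def test_k_exceeding_variable_count_rejected(self):
        M = pd.DataFrame(np.eye(5), columns=[f"v{i}" for i in range(5)])
        sca = sca_decompose(M, n_components=1)
        with pytest.raises(ValueError, match="exceeds"):
            rank_loadings(sca, component=1, k=12)

    def test_extremes_identified(self):
        M = pd.DataFrame(
            np.outer(np.arange(1, 7), [0.9, -0.9, 0.1]),
            columns=["up", "down", "small"],
        )
        sca = sca_decompose(M, n_components=1)
        ranked = rank_loadings(sca, component=1, k=1)
        assert ranked.loc[ranked["direction"] == "top", "variable"].item() == "up"
        assert ranked.loc[ranked["direction"] == "bottom", "variable"].item() == "down"

    def test_stable_under_variable_permutation(self, benchmark_fit):
        _table, _truth, fit = benchmark_fit
        sca = fit.sca_for("combined")
        shuffled = sca.loadings.sample(frac=1.0, random_state=0)
        from volatempo.rmasca import ScaResult

        sca2 = ScaResult(scores=sca.scores, loadings=shuffled,
                         explained_pct=sca.explained_pct)
        a = rank_loadings(sca, 1, 5).reset_index(drop=True)
        b = rank_loadings(sca2, 1, 5).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
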