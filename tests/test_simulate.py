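import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from volatempo import (GroundTruth, NoiseModel, TrajectoryTemplate,
                       make_design, simulate_alkane_ladder,
                       simulate_peak_table, simulate_spectral_library,
                       simulate_tensor)
from volatempo.simulate import study_templates


class TestDesign:
    def test_default_reproduces_study_layout(self, study_design):
        assert study_design.groups == ("I", "O", "FM", "SM")
        assert len(study_design.time_points_h) == 7
        assert study_design.n_cells == 84
        cells = study_design.cells()
        assert len(cells) == len(set(cells)) == 84
        assert study_design.inoculated["SM"] is False

    def test_small_design_cell_count(self):
        d = make_design(groups=["A", "B"], time_points_h=[0, 1, 2], replicates=1)
        assert d.n_cells == 6

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"time_points_h": [0, 0, 4]},
            {"groups": ["A", "A", "B"]},
            {"groups": ["A"]},
            {"time_points_h": [0, 4]},
            {"replicates": 0},
            {"time_points_h": [4, 0, 8]},
        ],
    )
    def test_invalid_designs_rejected(self, kwargs):
        base = dict(groups=["A", "B"], time_points_h=[0, 4, 8], replicates=2)
        base.update(kwargs)
        with pytest.raises(ValueError):
            make_design(**base)


class TestTemplates:
    def test_constant_returns_baseline_everywhere(self):
        tpl = TrajectoryTemplate("constant", baseline_level=42.0)
        t = np.array([0.0, 4.0, 24.0])
        assert np.array_equal(tpl(t), np.full(3, 42.0))

    def test_logistic_rise_monotone_and_saturating(self):
        tpl = TrajectoryTemplate("logistic-rise", baseline_level=10.0,
                                 amplitude=90.0, rise_midpoint_h=6.0, rate=1.0)
        t = np.arange(0, 25, 4.0)
        y = tpl(t)
        assert np.all(np.diff(y) >= 0)
        assert y[-1] == pytest.approx(100.0, abs=0.01)
        # direct evaluation of the logistic closed form
        expected = 10.0 + 90.0 / (1.0 + np.exp(-(t - 6.0)))
        np.testing.assert_allclose(y, expected, rtol=1e-12)

    @given(st.sampled_from(["constant", "logistic-rise", "exponential-decay",
                            "early-bump"]),
           st.floats(0, 1e3), st.floats(-1e3, 1e3), st.floats(0.01, 10))
    @settings(max_examples=50, deadline=None)
    def test_templates_finite_on_design_grid(self, kind, base, amp, rate):
        tpl = TrajectoryTemplate(kind, baseline_level=base, amplitude=amp,
                                 rise_midpoint_h=6.0, rate=rate)
        y = tpl(np.array([0, 4, 8, 12, 16, 20, 24], dtype=float))
        assert np.all(np.isfinite(y))

    def test_unknown_kind_and_bad_rate_rejected(self):
        with pytest.raises(ValueError):
            TrajectoryTemplate("sigmoid")
        with pytest.raises(ValueError):
            TrajectoryTemplate("constant", rate=0.0)


class TestPeakTable:
    def test_noiseless_run_returns_template_values_exactly(self, study_design):
        tpl = TrajectoryTemplate("constant", baseline_level=100.0)
        templates = {("x", g): tpl for g in study_design.groups}
        table, truth = simulate_peak_table(study_design, templates,
                                           NoiseModel(), seed=0)
        assert (table["intensity"] == 100.0).all()
        assert len(table) == study_design.n_cells

    def test_seed_determinism_byte_identical(self, study_design, small_templates):
        templates, _ = small_templates
        noise = NoiseModel(multiplicative_cv=0.2, additive_sd=1.0,
                           missing_below=5.0)
        t1, _ = simulate_peak_table(study_design, templates, noise, seed=7)
        t2, _ = simulate_peak_table(study_design, templates, noise, seed=7)
        assert t1.to_csv(index=False) == t2.to_csv(index=False)
        t3, _ = simulate_peak_table(study_design, templates, noise, seed=8)
        assert t1.to_csv(index=False) != t3.to_csv(index=False)

    def test_detection_threshold_yields_missing_not_zero(self, study_design):
        tpl = TrajectoryTemplate("constant", baseline_level=1.0)
        templates = {("x", g): tpl for g in study_design.groups}
        noise = NoiseModel(additive_sd=1.0, missing_below=1.0)
        table, _ = simulate_peak_table(study_design, templates, noise, seed=0)
        assert table["intensity"].isna().any()
        assert (table["intensity"].dropna() >= 1.0).all()

    def test_missing_template_for_group_is_error(self, study_design):
        templates = {("x", "I"): TrajectoryTemplate("constant", baseline_level=1)}
        with pytest.raises(ValueError, match="no template"):
            simulate_peak_table(study_design, templates)

    def test_negative_noise_parameters_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(multiplicative_cv=-0.1)

    def test_sterile_group_templates_are_constant(self, study_design,
                                                  small_templates):
        templates, class_map = small_templates
        for (compound, group), tpl in templates.items():
            if group == "SM":
                assert tpl.kind == "constant"


class TestTensor:
    def test_noiseless_crossproduct_invariance_is_exact(self, noiseless_tensor):
        _tensor, truth = noiseless_tensor
        assert truth.cross_product_deviation() == 0.0

    def test_rank1_slabs_are_rank_one(self):
        tensor, truth = simulate_tensor(n_scans=60, mz_axis=np.arange(35, 76),
                                        n_samples=4, n_components=1, seed=3)
        for slab in tensor.slabs:
            s = np.linalg.svd(slab, compute_uv=False)
            assert s[1] < 1e-10 * s[0]

    def test_default_mz_axis_spans_instrument_scan_range(self):
        tensor, _ = simulate_tensor(n_scans=80, n_samples=4, n_components=2,
                                    seed=0)
        assert tensor.mz_axis[0] == 35
        assert tensor.mz_axis[-1] == 350

    def test_shift_exceeding_window_rejected(self):
        with pytest.raises(ValueError, match="scan window"):
            simulate_tensor(n_scans=30, mz_axis=np.arange(35, 56),
                            n_samples=4, n_components=2,
                            shift_range_scans=20, seed=0)

    def test_snr_injection_matches_requested_power(self):
        tensor0, truth = simulate_tensor(n_scans=100, mz_axis=np.arange(35, 76),
                                         n_samples=8, n_components=2,
                                         noise_snr_db=None, seed=5)
        tensor1, _ = simulate_tensor(n_scans=100, mz_axis=np.arange(35, 76),
                                     n_samples=8, n_components=2,
                                     noise_snr_db=20.0, seed=5)
        signal = np.concatenate([s.ravel() for s in tensor0.slabs])
        noise = np.concatenate(
            [(a - b).ravel() for a, b in zip(tensor1.slabs, tensor0.slabs)]
        )
        snr_db = 10 * np.log10(np.mean(signal**2) / np.mean(noise**2))
        assert snr_db == pytest.approx(20.0, abs=0.5)


class TestAlkaneLadder:
    def test_default_c8_c20_has_13_entries(self):
        ladder = simulate_alkane_ladder()
        assert len(ladder) == 13
        assert ladder[0][0] == 8 and ladder[-1][0] == 20
        times = [t for _c, t in ladder]
        assert all(b > a for a, b in zip(times, times[1:]))

    def test_arithmetic_progression(self):
        ladder = simulate_alkane_ladder(t_first=10.0, spacing=2.0)
        assert dict(ladder)[10] == pytest.approx(14.0)

    @pytest.mark.parametrize("kwargs", [{"spacing": -1.0}, {"spacing": 0.0},
                                        {"c_min": 20, "c_max": 8},
                                        {"c_min": 8, "c_max": 8}])
    def test_invalid_ladders_rejected(self, kwargs):
        with pytest.raises(ValueError):
            simulate_alkane_ladder(**kwargs)


class TestSpectralLibrary:
    def test_entries_are_nonnegative_and_nonzero(self):
        lib = simulate_spectral_library(5, seed=0)
        for spec in lib:
            assert np.all(spec.peaks.intensities >= 0)
            assert spec.peaks.intensities.sum() > 0

    def test_seed_determinism(self):
        a = simulate_spectral_library(4, seed=3)
        b = simulate_spectral_library(4, seed=3)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.peaks.mz, sb.peaks.mz)
            np.testing.assert_array_equal(sa.peaks.intensities,
                                          sb.peaks.intensities)

    def test_sparsity_bounds_enforced(self):
        with pytest.raises(ValueError):
            simulate_spectral_library(2, sparsity=0.0)
        with pytest.raises(ValueError):
            simulate_spectral_library(2, sparsity=1.5)


class TestGroundTruth:
    def test_json_round_trip_preserves_templates_and_factors(
        self, study_design, small_templates, noiseless_tensor
    ):
        templates, _ = small_templates
        _tensor, factors = noiseless_tensor
        gt = GroundTruth(templates=dict(templates), factors=factors)
        back = GroundTruth.from_json(gt.to_json())
        assert set(back.templates) == set(gt.templates)
        for key in gt.templates:
            assert back.templates[key] == gt.templates[key]
        np.testing.assert_array_equal(back.factors.spectra, factors.spectra)
        np.testing.assert_array_equal(back.factors.concentrations,
                                      factors.concentrations)
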