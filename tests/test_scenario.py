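import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lakechla.data import PREDICTORS, SEASONS, compute_norm_stats
from lakechla.ensemble import EnsembleModel, ForestHyperparams, predict_forest
from lakechla.scenario import (
    DEFAULT_AXIS,
    PressureMultipliers,
    ScenarioGrid,
    apply_multipliers,
    characterize_curve_shape,
    delta_chla_contrast,
    evaluate_grid,
    find_compensation,
    find_recovery_threshold,
    mean_response_curve,
    percent_change,
    policy_scenario_2030,
    rebalance_landcover,
    _scenario_feature_block,
)
from lakechla.synthetic import SyntheticConfig, generate_lakes, true_response
from tests.test_data import make_record


class TestRebalance:
    @pytest.mark.parametrize(
        "cover,m,expected",
        [
            ((20, 60, 20), 1.0, (20, 60, 20)),
            ((20, 60, 20), 2.0, (40, 45, 15)),
            ((20, 60, 20), 0.0, (0, 75, 25)),
            ((76, 18, 6), 2.0, (100, 0, 0)),  # LI capped at 100
        ],
    )
    def test_stated_rule(self, cover, m, expected):
        assert rebalance_landcover(*cover, m) == pytest.approx(expected)

    def test_all_urban_fallback_split(self):
        li, la, lf = rebalance_landcover(100.0, 0.0, 0.0, 0.5, fallback_ratio=0.25)
        assert (li, la, lf) == pytest.approx((50.0, 12.5, 37.5))

    def test_bad_composition_rejected(self):
        with pytest.raises(ValueError, match="sum to 100"):
            rebalance_landcover(20, 50, 20, 1.0)

    @given(
        li=st.floats(0, 100),
        la_share=st.floats(0, 1),
        m=st.floats(0, 2),
    )
    @settings(max_examples=200, deadline=None)
    def test_conservation_and_ratio_preservation(self, li, la_share, m):
        la = (100.0 - li) * la_share
        lf = 100.0 - li - la
        li2, la2, lf2 = rebalance_landcover(li, la, lf, m)
        assert abs(li2 + la2 + lf2 - 100.0) <= 1e-9
        assert 0 <= li2 <= 100 and la2 >= -1e-12 and lf2 >= -1e-12
        if la + lf > 0 and li2 < 100:
            # share comparison avoids cancellation at extreme LA:LF ratios
            assert la2 / (la2 + lf2) == pytest.approx(la / (la + lf), abs=1e-9)


class TestApplyMultipliers:
    def test_identity(self):
        rec = make_record()
        assert apply_multipliers(rec, PressureMultipliers(1.0, 1.0)) == rec

    def test_s_scaling(self):
        rec = make_record(s_ratio=33.8)
        out = apply_multipliers(rec, PressureMultipliers(0.7, 1.0))
        assert out.s_ratio == pytest.approx(23.66)
        assert rec.s_ratio == 33.8  # original unmodified

    def test_untouched_fields(self):
        rec = make_record()
        out = apply_multipliers(rec, PressureMultipliers(0.5, 2.0))
        for f in ("lake_area", "depth_D", "catchment_area", "drainage_density_Id", "altitude"):
            assert getattr(out, f) == getattr(rec, f)

    def test_negative_multipliers_rejected(self):
        with pytest.raises(ValueError):
            PressureMultipliers(-0.1, 1.0)


class TestPercentChange:
    def test_identity_is_zero(self):
        assert percent_change(5.0, 5.0) == 0.0

    @pytest.mark.parametrize(
        "baseline,scenario,expected",
        [(43.1, 38.2, -11.4), (7.4, 6.5, -12.2), (3.3, 2.2, -33.3)],
    )
    def test_one_decimal_values(self, baseline, scenario, expected):
        assert round(percent_change(baseline, scenario), 1) == expected

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)


class TestGrid:
    def test_default_axis_has_101_points(self):
        assert len(DEFAULT_AXIS) == 101
        assert DEFAULT_AXIS[0] == 0.0 and DEFAULT_AXIS[-1] == 2.0
        assert DEFAULT_AXIS[51] - DEFAULT_AXIS[50] == pytest.approx(0.02)

    def test_identity_cell_equals_baseline_predictions(self, dataset48, fitted48, coarse_grid):
        _, records, _, _ = dataset48
        X = _scenario_feature_block(records, fitted48.regressor.norm, 1.0, 1.0)
        preds = predict_forest(fitted48.regressor, X)
        mean, freq = coarse_grid.cell(1.0, 1.0, "all")
        assert mean == preds.mean()  # bit-exact identity scenario
        assert freq == 100.0 * np.mean(preds > 25.0)

    def test_vectorised_block_matches_per_record_route(self, dataset48, fitted48):
        from lakechla.data import encode_features

        _, records, _, _ = dataset48
        norm = fitted48.regressor.norm
        for m_s, m_li in ((0.4, 1.6), (1.2, 0.0), (0.0, 2.0)):
            X = _scenario_feature_block(records, norm, m_s, m_li)
            manual = []
            for season in SEASONS:
                for rec in records:
                    transformed = apply_multipliers(rec, PressureMultipliers(m_s, m_li))
                    manual.append(encode_features(transformed, season, norm))
            np.testing.assert_allclose(X, np.array(manual), atol=1e-12)

    def test_grid_shape_and_dataframe(self, coarse_grid):
        assert coarse_grid.mean_chla["all"].shape == (21, 21)
        df = coarse_grid.to_dataframe()
        assert len(df) == 21 * 21 * 3
        assert list(df.columns) == ["m_s", "m_li", "stratum", "mean_chla", "pct_eutrophic"]
        assert df["pct_eutrophic"].between(0, 100).all()

    def test_constant_model_gives_flat_grid(self, dataset48):
        _, records, observations, _ = dataset48
        norm = compute_norm_stats(records, observations)
        from lakechla.ensemble import fit_forest
        from lakechla.data import build_feature_matrix

        X = build_feature_matrix(records, observations, norm)
        model = fit_forest(X, np.full(len(observations), 30.0), "regression",
                           ForestHyperparams(n_trees=10), norm)
        grid = evaluate_grid(model, None, records, m_s_axis=(0.0, 1.0, 2.0),
                             m_li_axis=(0.0, 1.0, 2.0))
        assert np.ptp(grid.mean_chla["all"]) == 0.0
        assert np.all(grid.pct_eutrophic["all"] == 100.0)

    def test_single_stratum_dataset_warns(self, dataset48, fitted48):
        _, records, _, _ = dataset48
        drainage_only = [r for r in records if r.connectivity == "drainage"]
        with pytest.warns(UserWarning, match="seepage"):
            grid = evaluate_grid(fitted48.regressor, None, drainage_only,
                                 m_s_axis=(1.0,), m_li_axis=(1.0,))
        assert set(grid.mean_chla) == {"all", "drainage"}

    def test_monotone_truth_gives_monotone_surface(self, dataset48):
        """Plugging the generative response in as the predictor, mean Chla
        never decreases with the load multiplier in any grid column."""
        cfg, records, observations, _ = dataset48
        norm = compute_norm_stats(records, observations)

        class TruthPredictor:
            def predict(self, X):
                out = np.empty(len(X))
                means = np.asarray(norm.means)
                sds = np.asarray(norm.sds)
                for i, row in enumerate(X):
                    vals = row[: len(PREDICTORS)] * sds + means
                    season = SEASONS[int(np.argmax(row[len(PREDICTORS):]))]
                    rec = make_record(
                        s_ratio=max(vals[0], 0.0),
                        lf_pct=vals[1], la_pct=vals[2], li_pct=vals[3],
                        drainage_density_Id=vals[4], depth_D=vals[5], altitude=vals[6],
                    )
                    out[i] = true_response(rec, season, cfg)
                return out

        model = EnsembleModel("regression", TruthPredictor(), ForestHyperparams(), norm)
        axis = tuple(np.round(np.arange(0.0, 2.0001, 0.25), 10))
        grid = evaluate_grid(model, None, records, m_s_axis=axis, m_li_axis=axis)
        surface = grid.mean_chla["all"]
        assert np.all(np.diff(surface, axis=0) >= -1e-9)


class TestCurves:
    def test_slice_matches_grid_cells(self, coarse_grid):
        ms, curve = mean_response_curve(coarse_grid, "m_S", 1.0, "drainage")
        assert len(curve) == 21
        j = list(coarse_grid.m_li_axis).index(1.0)
        np.testing.assert_array_equal(curve, coarse_grid.mean_chla["drainage"][:, j])

    def test_off_grid_fixed_value_rejected(self, coarse_grid):
        with pytest.raises(ValueError, match="not on the grid"):
            mean_response_curve(coarse_grid, "m_S", 1.01, "all")

    def test_saturating_family_recognised(self):
        m = np.asarray(DEFAULT_AXIS)
        out = characterize_curve_shape(m, m / (0.1 + m))
        assert out["shape"] == "saturating"

    def test_linear_family_recognised(self):
        m = np.asarray(DEFAULT_AXIS)
        out = characterize_curve_shape(m, 0.2 + 0.5 * m)
        assert out["shape"] == "linear"

    def test_constant_curve_is_linear(self):
        m = np.asarray(DEFAULT_AXIS)
        assert characterize_curve_shape(m, np.full_like(m, 3.0))["shape"] == "linear"

    def test_short_or_nonfinite_curves_rejected(self):
        with pytest.raises(ValueError):
            characterize_curve_shape([0, 1, 2], [1, 2, 3])
        with pytest.raises(ValueError, match="finite"):
            characterize_curve_shape([0, 0.5, 1, 1.5, 2], [1, 2, np.nan, 3, 4])


class TestDeltaContrast:
    def test_pressure_index_arithmetic(self, fitted48):
        rec = make_record(li_pct=10.0, la_pct=40.0, lf_pct=50.0, catchment_area=2.0,
                          lake_area=10.0, s_ratio=20.0)
        (dc,) = delta_chla_contrast(fitted48.regressor, [rec])
        assert dc.pressure_index == pytest.approx(0.5)

    def test_zero_li_gives_zero_index(self, fitted48):
        rec = make_record(li_pct=0.0, la_pct=40.0, lf_pct=60.0)
        (dc,) = delta_chla_contrast(fitted48.regressor, [rec])
        assert dc.pressure_index == 0.0

    def test_la_floor_guard(self, fitted48):
        rec = make_record(li_pct=50.0, la_pct=0.0, lf_pct=50.0, catchment_area=4.0,
                          lake_area=10.0, s_ratio=40.0)
        (dc,) = delta_chla_contrast(fitted48.regressor, [rec])
        assert dc.pressure_index == pytest.approx(50.0 / 1.0 * 4.0)

    def test_landcover_blind_model_gives_zero_delta(self, dataset48):
        _, records, observations, _ = dataset48
        norm = compute_norm_stats(records, observations)

        class SOnly:
            def predict(self, X):
                return 10.0 + X[:, 0]

        model = EnsembleModel("regression", SOnly(), ForestHyperparams(), norm)
        for dc in delta_chla_contrast(model, records):
            assert dc.delta_chla == pytest.approx(0.0, abs=1e-12)


def make_grid_from_freq(freq_fn, axis=None):
    """Hand-built frequency surface grid (mean Chla unused)."""
    axis = axis if axis is not None else np.round(np.arange(0.0, 2.0001, 0.02), 10)
    f = np.array([[freq_fn(ms, ml) for ml in axis] for ms in axis])
    return ScenarioGrid(
        m_s_axis=tuple(axis),
        m_li_axis=tuple(axis),
        mean_chla={"all": np.zeros_like(f)},
        pct_eutrophic={"all": f},
    )


class TestRecoveryAndCompensation:
    def test_linear_frequency_curve(self):
        grid = make_grid_from_freq(lambda ms, ml: max(0.0, 100.0 * (ms - 0.5)))
        assert find_recovery_threshold(grid, "all", "all_recovered") == pytest.approx(0.5)

    def test_baseline_already_recovered(self):
        grid = make_grid_from_freq(lambda ms, ml: 0.0)
        assert find_recovery_threshold(grid, "all", "all_recovered") == 0.0
        assert find_recovery_threshold(grid, "all", "frequency_halved") == 0.0

    def test_constant_positive_not_reached(self):
        grid = make_grid_from_freq(lambda ms, ml: 40.0)
        assert find_recovery_threshold(grid, "all", "all_recovered") is None

    def test_frequency_halved(self):
        grid = make_grid_from_freq(lambda ms, ml: 100.0 * ms)
        # baseline 100 at m_S=1; halved at the largest m_S with freq <= 50
        assert find_recovery_threshold(grid, "all", "frequency_halved") == pytest.approx(0.5)

    def test_compensation_closed_form(self):
        grid = make_grid_from_freq(
            lambda ms, ml: 100.0 * max(0.0, ms + 0.3 * (ml - 1.0) - 0.5)
        )
        # at m_S=0.52 the frequency is already 2% at m_LI=1
        assert find_compensation(grid, "all", 0.52, 2.0) == pytest.approx(1.0)
        # restoring the baseline 50% needs m_LI = 2.6, off the [0,2] grid
        assert find_compensation(grid, "all", 0.52, 50.0) is None

    def test_compensation_reference_zero(self):
        grid = make_grid_from_freq(lambda ms, ml: 10.0 * ml)
        assert find_compensation(grid, "all", 1.0, 0.0) == pytest.approx(1.0)

    def test_flat_surface_below_reference(self):
        grid = make_grid_from_freq(lambda ms, ml: 1.0)
        assert find_compensation(grid, "all", 1.0, 50.0) is None

    def test_finders_match_exhaustive_scan_oracle(self):
        """Random monotone-ish surfaces: finders agree with brute force."""
        rng = np.random.default_rng(7)
        axis = np.round(np.arange(0.0, 2.0001, 0.1), 10)
        for trial in range(20):
            base = rng.uniform(0, 100, size=(len(axis), len(axis)))
            surf = np.maximum.accumulate(np.maximum.accumulate(base, axis=0), axis=1)
            if rng.random() < 0.3:
                surf = np.zeros_like(surf)
            grid = ScenarioGrid(tuple(axis), tuple(axis),
                                {"all": np.zeros_like(surf)}, {"all": surf})
            j1 = list(axis).index(1.0)
            i1 = j1
            # brute-force all_recovered / frequency_halved
            col = surf[:, j1]
            cands = [ms for i, ms in enumerate(axis) if ms <= 1.0 + 1e-9 and col[i] <= 0.0]
            expect = (1.0 - max(cands)) if cands else None
            got = find_recovery_threshold(grid, "all", "all_recovered")
            assert (got is None and expect is None) or got == pytest.approx(expect)
            half = col[i1] / 2
            cands = [ms for i, ms in enumerate(axis) if ms <= 1.0 + 1e-9 and col[i] <= half]
            expect = (1.0 - max(cands)) if cands else None
            got = find_recovery_threshold(grid, "all", "frequency_halved")
            assert (got is None and expect is None) or got == pytest.approx(expect)
            # brute-force compensation at a random fixed m_S and reference
            i_fix = int(rng.integers(len(axis)))
            ref = float(rng.uniform(0, 100))
            row = surf[i_fix, :]
            cands = [ml for j, ml in enumerate(axis) if ml >= 1.0 - 1e-9 and row[j] >= ref]
            expect = min(cands) if cands else None
            got = find_compensation(grid, "all", float(axis[i_fix]), ref)
            assert (got is None and expect is None) or got == pytest.approx(expect)


class TestPolicyScenario:
    def test_identity_multipliers_give_zero_change(self, dataset48, fitted48):
        _, records, observations, _ = dataset48
        report = policy_scenario_2030(
            fitted48.regressor, fitted48.classifier, records, observations,
            multipliers=(1.0, 1.0),
        )
        for row in report.strata.values():
            assert row["pct_change_mean_chla"] == 0.0
            assert row["scenario_mean_chla"] == row["baseline_mean_chla"]

    def test_report_structure(self, dataset48, fitted48):
        _, records, observations, _ = dataset48
        report = fitted48.policy_scenario()
        assert report.multipliers == (0.70, 1.20)
        assert set(report.strata) == {"all", "drainage", "seepage"}
        row = report.strata["drainage"]
        assert row["pct_change_mean_chla"] == pytest.approx(
            percent_change(row["baseline_mean_chla"], row["scenario_mean_chla"])
        )
        text = report.summary_text()
        assert "drainage" in text and "model baseline" in text

    def test_json_round_trip(self, dataset48, fitted48, tmp_path):
        import json

        report = fitted48.policy_scenario()
        report.to_json(tmp_path / "policy.json")
        loaded = json.loads((tmp_path / "policy.json").read_text())
        assert loaded["multipliers"]["m_S"] == 0.70
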