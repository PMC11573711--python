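import numpy as np
import pytest

from treelim.model import (
    Control,
    ControlSpec,
    ModelParams,
    control_index,
    count_free_parameters,
    default_control_spec,
    energy_factor,
    limitation_curve,
    scale_factor,
    transform_map,
    tree_cover,
    tree_cover_without,
)

from hypothesis import given, settings, strategies as st

from oracles import random_predictors, random_valid_params, scalar_tree_cover


@settings(max_examples=80, derandomize=True)
@given(x0=st.floats(-10, 10), k=st.floats(-50, 50),
       a=st.floats(-20, 20), b=st.floats(-20, 20))
def test_limitation_curve_bounded_and_monotone(x0, k, a, b):
    lo, hi = sorted((a, b))
    fa, fb = limitation_curve(np.array([lo, hi]), x0, k)
    assert 0.0 <= fa <= 1.0 and 0.0 <= fb <= 1.0
    if k >= 0:
        assert fa <= fb + 1e-12
    else:
        assert fa >= fb - 1e-12


class TestParameterCount:
    def test_standard_five_control_structure_has_23(self, spec):
        assert count_free_parameters(spec) == 23
        assert len(spec.param_names()) == 23

    def test_single_control_with_sigma_only(self):
        toy = ControlSpec(controls=(Control("map", +1, driver="map_mm"),),
                          extra_params=("sigma",))
        assert count_free_parameters(toy) == 3  # x0, k, sigma

    def test_removing_wind_drops_weight_and_exponent(self):
        no_wind = ControlSpec(controls=(
            Control("map", +1, driver="map_mm"),
            Control("mat", +1, driver="mat_c"),
            Control("sw", +1, driver="sw_wm2"),
            Control("stress", -1, factors=("burnt_area", "seasonality", "mtwm_c"),
                    exponents_free=True),
            Control("human", -1, factors=("pop_density", "urban", "cropland", "pasture")),
        ))
        assert count_free_parameters(no_wind) == 21


class TestTransforms:
    def test_map_transform_values(self):
        assert transform_map(np.array([0.0]), 100)[0] == pytest.approx(np.log(0.01))
        assert transform_map(np.array([999.99]), 100)[0] == pytest.approx(np.log(1000.0))

    def test_map_transform_monotone(self):
        x = np.linspace(0, 3000, 50)
        out = transform_map(x, 2000)
        assert np.all(np.diff(out) > 0)

    def test_map_transform_validates(self):
        with pytest.raises(ValueError):
            transform_map(np.array([1.0]), 0)
        with pytest.raises(ValueError):
            transform_map(np.array([-1.0]), 10)

    def test_scale_factor_endpoints_identity_and_worked_value(self):
        assert scale_factor(np.array([10.0]), (10, 45))[0] == 0.0
        assert scale_factor(np.array([45.0]), (10, 45))[0] == 1.0
        x = np.array([0.0, 0.3, 1.0])
        assert np.array_equal(scale_factor(x, (0.0, 1.0)), x)
        assert scale_factor(np.array([35.0]), (10, 45))[0] == pytest.approx(0.71429, abs=1e-5)
        with pytest.raises(ValueError):
            scale_factor(x, (1.0, 1.0))


class TestControlIndex:
    def test_single_factor_identity(self):
        assert control_index(np.array([[0.3]]), np.array([1.0]), np.array([1.0]))[0] \
            == pytest.approx(0.3)

    def test_weighted_power_combination(self):
        out = control_index(np.array([[0.2], [0.5]]), np.array([1.0, 1.0]),
                            np.array([1.0, 2.0]))
        assert out[0] == pytest.approx(0.225)

    def test_zero_factors_give_zero(self):
        out = control_index(np.zeros((3, 4)), np.array([1.0, 0.5, 2.0]), np.ones(3))
        assert np.all(out == 0)

    def test_validation(self):
        with pytest.raises(ValueError):
            control_index(np.zeros((2, 1)), np.ones(3), np.ones(3))
        with pytest.raises(ValueError):
            control_index(np.zeros((2, 1)), np.array([0.5, 1.0]), np.ones(2))
        with pytest.raises(ValueError):
            control_index(np.zeros((2, 1)), np.ones(2), np.array([1.0, -1.0]))


class TestLimitationCurve:
    def test_midpoint_and_worked_value(self):
        assert limitation_curve(np.array([2.0]), 2.0, 5.0)[0] == 0.5
        assert limitation_curve(np.array([3.0]), 2.0, 2.0)[0] == pytest.approx(0.88080, abs=1e-5)

    def test_steep_suppressive_limit(self):
        assert limitation_curve(np.array([3.0]), 2.0, -500.0)[0] == pytest.approx(0.0, abs=1e-12)

    def test_energy_factor_is_product(self, true_params):
        p = true_params.copy()
        mat = np.array([p.x0["mat"]])
        sw = np.array([p.x0["sw"]])
        assert energy_factor(mat, sw, p)[0] == pytest.approx(0.25)
        # saturate SW: energy equals the MAT factor alone
        sw_hi = np.array([p.x0["sw"] + 1e4])
        mat_probe = np.array([p.x0["mat"] + 1.0 / p.k["mat"] * 2.0])
        expected = limitation_curve(mat_probe, p.x0["mat"], p.k["mat"])[0]
        assert energy_factor(mat_probe, sw_hi, p)[0] == pytest.approx(expected)


class TestTreeCover:
    def test_saturated_factors_reach_tc_max(self, spec):
        rng = np.random.default_rng(0)
        pred = random_predictors(spec, rng, 4, 4)
        p = random_valid_params(spec, rng)
        # saturate every control: huge k with midpoints far on the right side
        for c in spec.controls:
            p.k[c.name] = 500.0
            p.x0[c.name] = -1000.0 if c.sign > 0 else 1000.0
        p.tc_max = 0.8
        assert np.allclose(tree_cover(pred, p, spec), 0.8)

    def test_any_zero_factor_kills_cover(self, spec):
        rng = np.random.default_rng(1)
        pred = random_predictors(spec, rng, 4, 4)
        p = random_valid_params(spec, rng)
        p.k["map"] = 500.0
        p.x0["map"] = 1000.0  # map factor ~ 0
        assert np.allclose(tree_cover(pred, p, spec), 0.0, atol=1e-12)

    def test_matches_scalar_oracle(self, spec):
        rng = np.random.default_rng(2)
        pred = random_predictors(spec, rng)
        p = random_valid_params(spec, rng)
        assert np.allclose(tree_cover(pred, p, spec),
                           scalar_tree_cover(pred, p, spec), atol=1e-12)

    def test_monotone_in_drivers(self, spec):
        rng = np.random.default_rng(3)
        pred = random_predictors(spec, rng)
        p = random_valid_params(spec, rng)
        base = tree_cover(pred, p, spec)
        up = pred.subset(np.arange(pred.n_cells))
        up.single["map"] = up.single["map"] + 0.5
        assert np.all(tree_cover(up, p, spec) >= base)
        worse = pred.subset(np.arange(pred.n_cells))
        worse.composite["stress"] = np.clip(worse.composite["stress"] + 0.1, 0, 1)
        assert np.all(tree_cover(worse, p, spec) <= base + 1e-12)

    def test_cover_vanishes_with_rainfall(self, spec):
        rng = np.random.default_rng(4)
        pred = random_predictors(spec, rng, 3, 3)
        p = random_valid_params(spec, rng)
        pred.single["map"] = np.full(pred.n_cells, np.log(1e-6))
        assert np.all(tree_cover(pred, p, spec) < 1e-2)


class TestTreeCoverWithout:
    def test_zero_weight_factor_is_noop(self, spec):
        rng = np.random.default_rng(5)
        pred = random_predictors(spec, rng)
        p = random_valid_params(spec, rng)
        p.weights["stress"][3] = 0.0  # wind
        assert np.allclose(tree_cover_without(pred, p, spec, "wind_ms"),
                           tree_cover(pred, p, spec), atol=1e-12)

    def test_control_removal_divides_out_its_factor(self, spec):
        rng = np.random.default_rng(6)
        pred = random_predictors(spec, rng)
        p = random_valid_params(spec, rng)
        tc = tree_cover(pred, p, spec)
        from treelim.model import limitation_curve as f

        factor = f(pred.single["mat"], p.x0["mat"], p.k["mat"])
        assert np.allclose(tree_cover_without(pred, p, spec, "mat"),
                           tc / factor, atol=1e-12)

    def test_factor_removal_renormalises_index(self, spec):
        rng = np.random.default_rng(7)
        pred = random_predictors(spec, rng)
        p = random_valid_params(spec, rng)
        for target in ("burnt_area", "seasonality", "urban"):
            assert np.allclose(tree_cover_without(pred, p, spec, target),
                               scalar_tree_cover(pred, p, spec, removed=target),
                               atol=1e-12)

    def test_unknown_target_rejected(self, spec, small_pred, true_params):
        with pytest.raises(KeyError):
            tree_cover_without(small_pred, true_params, spec, "soil_texture")


class TestParamsVector:
    def test_round_trip_and_dict(self, spec, true_params):
        v = true_params.to_vector(spec)
        assert v.size == 23
        back = ModelParams.from_vector(v, spec)
        assert np.allclose(back.to_vector(spec), v)
        d = true_params.to_dict(spec)
        assert d["tc_max"] == true_params.tc_max
        assert d["v_stress_seasonality"] == true_params.weights["stress"][1]

    def test_wrong_length_rejected(self, spec):
        with pytest.raises(ValueError):
            ModelParams.from_vector(np.zeros(10), spec)
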