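import numpy as np
import pytest

from treelim.impacts import (
    ImpactDistribution,
    absolute_impact,
    bhattacharyya,
    ensemble_impact,
    fire_increment_experiment,
    fire_without_humans,
    fire_without_humans_and_ba,
    limitation,
    pairwise_difference_probability,
    quantile_summary,
    relative_impact,
    response_curve,
    sensitivity,
)
from treelim.model import Predictors, limitation_curve, tree_cover, tree_cover_without

from oracles import (
    random_predictors,
    random_valid_params,
    scalar_absolute_impact,
    scalar_limitation,
    scalar_relative_impact,
    scalar_sensitivity,
)


def single_cell_pred(spec, stress=None, human=None, map_star=7.0, mat=25.0, sw=220.0):
    single = {"map": np.array([map_star]), "mat": np.array([mat]), "sw": np.array([sw])}
    composite = {
        "stress": np.array(stress if stress is not None else [0.2, 0.3, 0.1, 0.0]).reshape(4, 1),
        "human": np.array(human if human is not None else [0.1, 0.0, 0.2, 0.1]).reshape(4, 1),
    }
    return Predictors(single, composite, np.ones((1, 1), bool),
                      np.array([0.25]), np.array([0.25]))


class TestPointImpacts:
    def test_zero_weight_factor_has_zero_impact(self, spec):
        rng = np.random.default_rng(0)
        pred = random_predictors(spec, rng)
        p = random_valid_params(spec, rng)
        p.weights["human"][1] = 0.0  # urban
        assert np.allclose(absolute_impact(pred, p, spec, "urban"), 0.0, atol=1e-12)
        assert np.allclose(relative_impact(pred, p, spec, "urban"), 0.0, atol=1e-12)

    def test_control_impact_follows_product_structure(self, spec):
        rng = np.random.default_rng(1)
        pred = random_predictors(spec, rng)
        p = random_valid_params(spec, rng)
        tc = tree_cover(pred, p, spec)
        f = limitation_curve(pred.single["mat"], p.x0["mat"], p.k["mat"])
        # TC_* = TC / f, impact = TC/f - TC; relative impact = 1 - f
        assert np.allclose(absolute_impact(pred, p, spec, "mat"),
                           tc / f - tc, atol=1e-12)
        assert np.allclose(relative_impact(pred, p, spec, "mat"), 1 - f, atol=1e-12)

    def test_impact_bounded_by_unconstrained_cover(self, spec):
        rng = np.random.default_rng(2)
        pred = random_predictors(spec, rng)
        p = random_valid_params(spec, rng)
        for target in ("map", "stress", "human", "burnt_area"):
            ai = absolute_impact(pred, p, spec, target)
            ts = tree_cover_without(pred, p, spec, target)
            assert np.all(ai <= ts + 1e-12)

    def test_matches_scalar_oracles(self, spec):
        rng = np.random.default_rng(3)
        pred = random_predictors(spec, rng)
        p = random_valid_params(spec, rng)
        for target in ("map", "stress", "seasonality", "pasture"):
            assert np.allclose(absolute_impact(pred, p, spec, target),
                               scalar_absolute_impact(pred, p, spec, target), atol=1e-12)
            assert np.allclose(relative_impact(pred, p, spec, target),
                               scalar_relative_impact(pred, p, spec, target),
                               atol=1e-12, equal_nan=True)


class TestOverlap:
    def test_identical_distributions_overlap_fully(self):
        rng = np.random.default_rng(4)
        d = ImpactDistribution(rng.uniform(0, 1, (5, 50)))
        assert pairwise_difference_probability(d, d) == pytest.approx(1.0)

    def test_disjoint_supports_do_not_overlap(self):
        lo = ImpactDistribution(np.random.default_rng(5).uniform(0.0, 0.2, (5, 50)))
        hi = ImpactDistribution(np.random.default_rng(6).uniform(0.8, 1.0, (5, 50)))
        assert pairwise_difference_probability(lo, hi) == 0.0

    def test_two_bin_half_overlap(self):
        assert bhattacharyya(np.array([1.0, 0.0]), np.array([0.5, 0.5])) \
            == pytest.approx(np.sqrt(0.5))

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        a = ImpactDistribution(rng.beta(2, 5, (8, 40)))
        b = ImpactDistribution(rng.beta(5, 2, (8, 40)))
        assert pairwise_difference_probability(a, b) == \
            pytest.approx(pairwise_difference_probability(b, a))


class TestLimitation:
    def test_zero_stress_means_zero_limitation(self, spec, true_params):
        pred = single_cell_pred(spec, stress=[0.0, 0.0, 0.0, 0.0])
        assert limitation(pred, true_params, spec, "stress")[0] == pytest.approx(0.0)

    def test_map_midpoint_gives_half(self, spec, true_params):
        pred = single_cell_pred(spec, map_star=true_params.x0["map"])
        assert limitation(pred, true_params, spec, "map")[0] == pytest.approx(0.5)

    def test_suppressive_normalisation_ratio(self, spec, true_params):
        # choose k, x0 so f(at zero stress) = 0.8 and f(at X) = 0.4
        p = true_params.copy()
        k = 4.0
        p.k["stress"] = k
        p.x0["stress"] = np.log(4.0) / k          # expit(k*x0) = 0.8
        x = p.x0["stress"] + np.log(1.5) / k      # expit(-k(x-x0)) = 0.4
        p.weights["stress"] = np.array([1.0, 0.0, 0.0, 0.0])
        p.exponents["stress"] = np.ones(4)
        pred = single_cell_pred(spec, stress=[x, 0, 0, 0])
        assert limitation(pred, p, spec, "stress")[0] == pytest.approx(0.5, abs=1e-9)

    def test_limitation_in_unit_interval_and_matches_oracle(self, spec):
        rng = np.random.default_rng(8)
        pred = random_predictors(spec, rng)
        p = random_valid_params(spec, rng)
        for control in ("map", "mat", "sw", "stress", "human"):
            lim = limitation(pred, p, spec, control)
            assert np.all((lim >= -1e-12) & (lim <= 1.0))
            assert np.allclose(lim, scalar_limitation(pred, p, spec, control), atol=1e-12)


class TestSensitivity:
    def test_maximal_at_midpoint(self, spec, true_params):
        pred = single_cell_pred(spec, map_star=true_params.x0["map"])
        r = sensitivity(pred, true_params, spec, "map")
        ts = tree_cover_without(pred, true_params, spec, "map")
        assert r[0] == pytest.approx(ts[0])

    def test_vanishes_in_saturated_tails(self, spec, true_params):
        p = true_params.copy()
        pred = single_cell_pred(spec, map_star=p.x0["map"] + 100.0 / p.k["map"])
        assert sensitivity(pred, p, spec, "map")[0] == pytest.approx(0.0, abs=1e-12)

    def test_gradient_factor_worked_value(self, spec):
        from scipy.special import expit

        f = expit(2.0)  # 0.88080 to five figures
        assert 4 * f * (1 - f) == pytest.approx(0.41998, abs=1e-5)
        rng = np.random.default_rng(9)
        pred = random_predictors(spec, rng)
        p = random_valid_params(spec, rng)
        for control in ("map", "stress"):
            assert np.allclose(sensitivity(pred, p, spec, control),
                               scalar_sensitivity(pred, p, spec, control), atol=1e-12)


class TestFireExperiments:
    def test_increment_never_increases_cover(self, spec, small_pred, toy_ensemble):
        dist = fire_increment_experiment(small_pred, toy_ensemble, spec)
        assert np.all(dist.values >= -1e-12)

    def test_increment_zero_when_fire_removed_from_index(self, spec, small_pred,
                                                         toy_ensemble, true_params):
        from treelim.inference import PosteriorEnsemble

        p = true_params.copy()
        p.weights["stress"] = np.array([1.0, 1.0, 1.0, 1.0])
        p.exponents["stress"] = np.ones(4)
        # a steepness of zero makes the whole stress control flat: no response
        p.k["stress"] = 0.0
        ens = PosteriorEnsemble(p.to_vector(spec)[None, :], np.array([-1.0]),
                                spec.param_names(), spec)
        dist = fire_increment_experiment(small_pred, ens, spec)
        assert np.allclose(dist.values, 0.0, atol=1e-12)

    def test_increment_matches_brute_force(self, spec, small_pred, toy_ensemble):
        dist = fire_increment_experiment(small_pred, toy_ensemble, spec, delta=0.01)
        i = 3
        p = toy_ensemble.member(i)
        base = tree_cover(small_pred, p, spec)
        bumped = small_pred.subset(np.arange(small_pred.n_cells))
        bumped.composite["stress"] = bumped.composite["stress"].copy()
        bumped.composite["stress"][0] = np.clip(bumped.composite["stress"][0] + 0.01, 0, 1)
        assert np.allclose(dist.values[i], base - tree_cover(bumped, p, spec), atol=1e-12)

    def test_without_humans_equals_standard_when_human_flat(self, spec, small_pred,
                                                            true_params):
        from treelim.inference import PosteriorEnsemble

        p = true_params.copy()
        p.k["human"] = 0.0  # human factor constant: cancels in the relative measure
        ens = PosteriorEnsemble(p.to_vector(spec)[None, :], np.array([-1.0]),
                                spec.param_names(), spec)
        no_human = fire_without_humans(small_pred, ens, spec)
        standard = relative_impact(small_pred, p, spec, "burnt_area")
        assert np.allclose(no_human.values[0], standard, atol=1e-12, equal_nan=True)

    def test_counterfactual_identity_and_zero_fire(self, spec, small_pred, toy_ensemble):
        ba = small_pred.composite["stress"][0]
        same = fire_without_humans_and_ba(small_pred, toy_ensemble, spec,
                                          ba[None, :], seed=0)
        base = fire_without_humans(small_pred, toy_ensemble, spec)
        assert np.allclose(same.values, base.values, atol=1e-12, equal_nan=True)
        # an all-zero counterfactual burnt area is still renormalised out of the
        # stress index, so the comparison is against the same removal: not NaN
        zero = fire_without_humans_and_ba(small_pred, toy_ensemble, spec,
                                          np.zeros((1, small_pred.n_cells)), seed=1)
        assert np.all(np.isfinite(zero.values[np.isfinite(zero.values)]))

    def test_counterfactual_reproducible_and_validated(self, spec, small_pred, toy_ensemble):
        ba = np.stack([small_pred.composite["stress"][0] * s for s in (1.0, 1.2, 1.5)])
        ba = np.clip(ba, 0, 1)
        a = fire_without_humans_and_ba(small_pred, toy_ensemble, spec, ba, seed=7)
        b = fire_without_humans_and_ba(small_pred, toy_ensemble, spec, ba, seed=7)
        assert np.array_equal(a.values[np.isfinite(a.values)],
                              b.values[np.isfinite(b.values)])
        with pytest.raises(ValueError):
            fire_without_humans_and_ba(small_pred, toy_ensemble, spec,
                                       np.zeros((2, 3)), seed=0)


class TestResponseCurve:
    def test_zero_weight_factor_flat_response(self, spec, small_pred, true_params):
        from treelim.inference import PosteriorEnsemble

        p = true_params.copy()
        p.weights["human"][2] = 0.0  # cropland
        ens = PosteriorEnsemble(p.to_vector(spec)[None, :], np.array([-1.0]),
                                spec.param_names(), spec)
        curve = response_curve(small_pred, ens, spec, "cropland")
        assert np.allclose(curve["median"], 0.0, atol=1e-12)

    def test_single_cell_bin_matches_scalar_value(self, spec, true_params):
        from treelim.inference import PosteriorEnsemble

        pred = single_cell_pred(spec, human=[0.0, 0.0, 0.255, 0.0])
        ens = PosteriorEnsemble(true_params.to_vector(spec)[None, :], np.array([-1.0]),
                                spec.param_names(), spec)
        curve = response_curve(pred, ens, spec, "cropland")
        rel = relative_impact(pred, true_params, spec, "cropland")[0]
        a_bin = curve["bin_center"][curve["count"] > 0][0]
        assert curve["median"][curve["count"] > 0][0] == pytest.approx(rel / a_bin)

    def test_occupancy_counts_all_cells(self, spec, small_pred, toy_ensemble):
        curve = response_curve(small_pred, toy_ensemble, spec, "burnt_area")
        assert curve["count"].sum() <= small_pred.n_cells
        assert np.all(curve["q10"] <= curve["q90"] + 1e-12)


class TestQuantileSummary:
    def test_constant_ensemble_collapses(self):
        d = ImpactDistribution(np.full((5, 10), 0.42))
        lo, hi = quantile_summary(d)
        assert np.allclose(lo, 0.42) and np.allclose(hi, 0.42)

    def test_linear_interpolation_convention(self):
        d = ImpactDistribution(np.arange(0.1, 1.05, 0.1).reshape(10, 1))
        lo, hi = quantile_summary(d, (0.10, 0.90))
        assert lo[0] == pytest.approx(0.19)
        assert hi[0] == pytest.approx(0.91)

    def test_bounds_monotone_in_level(self, toy_ensemble, spec, small_pred):
        d = ensemble_impact(small_pred, toy_ensemble, spec, "stress")
        q = quantile_summary(d, (0.10, 0.35, 0.65, 0.90))
        assert np.all(np.diff(q, axis=0) >= -1e-12)
        with pytest.raises(ValueError):
            quantile_summary(ImpactDistribution(np.ones((1, 3))))
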