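"""Independent scalar reference implementations.

Pure-Python per-cell re-derivations of the forward model, likelihood and
impact measures, written with plain loops and ``math`` so they share no
code path with the vectorised package implementations they check.
"""

import math

import numpy as np


def _logistic(x):
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _control_value(pred, params, spec, c, i, removed_factor=None):
    if c.composite:
        num = 0.0
        den = 0.0
        for j, fname in enumerate(c.factors):
            w = 1.0 if j == 0 else float(params.weights[c.name][j])
            if fname == removed_factor:
                w = 0.0
            p = float(params.exponents[c.name][j])
            num += w * float(pred.composite[c.name][j, i]) ** p
            den += w
        x = num / den if den > 0 else 0.0
    else:
        x = float(pred.single[c.name][i])
    return _logistic(c.sign * params.k[c.name] * (x - params.x0[c.name]))


def scalar_tree_cover(pred, params, spec, removed=None):
    """Per-cell loop evaluation of TC, optionally with removals.

    ``removed`` is None, a control/factor name, or a list of them.
    """
    removed_list = [] if removed is None else ([removed] if isinstance(removed, str) else list(removed))
    control_names = {c.name for c in spec.controls}
    skip = {r for r in removed_list if r in control_names}
    factor_removed = {}
    for r in removed_list:
        if r not in control_names:
            for c in spec.controls:
                if r in c.factors:
                    factor_removed[c.name] = r
    out = np.empty(pred.n_cells)
    for i in range(pred.n_cells):
        tc = params.tc_max
        for c in spec.controls:
            if c.name in skip:
                continue
            tc *= _control_value(pred, params, spec, c, i,
                                 factor_removed.get(c.name))
        out[i] = tc
    return out


def scalar_log_likelihood(obs_values, tc, sigma, p0, clip=1e-6):
    total = 0.0
    for o, t in zip(obs_values, tc):
        pz = (1.0 - t * t) * (1.0 - p0)
        if o == 0.0:
            total += math.log(pz)
        else:
            oc = min(max(o, clip), 1 - clip)
            tcc = min(max(t, clip), 1 - clip)
            z = (math.log(oc / (1 - oc)) - math.log(tcc / (1 - tcc))) / sigma
            total += math.log(1.0 - pz) - 0.5 * z * z - math.log(sigma) \
                - 0.5 * math.log(2 * math.pi)
    return total


def scalar_absolute_impact(pred, params, spec, target):
    tc = scalar_tree_cover(pred, params, spec)
    ts = scalar_tree_cover(pred, params, spec, removed=target)
    return np.abs(ts - tc)


def scalar_relative_impact(pred, params, spec, target):
    tc = scalar_tree_cover(pred, params, spec)
    ts = scalar_tree_cover(pred, params, spec, removed=target)
    out = np.empty_like(tc)
    for i in range(tc.size):
        out[i] = (ts[i] - tc[i]) / ts[i] if ts[i] > 0 else np.nan
    return out


def scalar_limitation(pred, params, spec, control):
    c = spec.control(control)
    out = np.empty(pred.n_cells)
    for i in range(pred.n_cells):
        f = _control_value(pred, params, spec, c, i)
        if c.sign > 0:
            out[i] = 1.0 - f
        else:
            f0 = _logistic(c.sign * params.k[control] * (0.0 - params.x0[control]))
            out[i] = 1.0 - f / f0
    return out


def scalar_sensitivity(pred, params, spec, target):
    c = spec.control(target)
    ts = scalar_tree_cover(pred, params, spec, removed=target)
    out = np.empty(pred.n_cells)
    for i in range(pred.n_cells):
        f = _control_value(pred, params, spec, c, i)
        out[i] = 4.0 * f * (1.0 - f) * ts[i]
    return out


def random_predictors(spec, rng, nlat=10, nlon=10):
    """Random model-ready predictor arrays on a fully unmasked small grid."""
    from treelim.model import Predictors

    n = nlat * nlon
    single = {"map": rng.uniform(-2.0, 8.2, n),
              "mat": rng.uniform(5.0, 32.0, n),
              "sw": rng.uniform(150.0, 280.0, n)}
    composite = {"stress": rng.uniform(0.0, 1.0, (4, n)),
                 "human": rng.uniform(0.0, 1.0, (4, n))}
    lat = -29.75 + 0.5 * np.arange(nlat)
    lon = -179.75 + 0.5 * np.arange(nlon)
    return Predictors(single, composite, np.ones((nlat, nlon), bool), lat, lon)


def random_valid_params(spec, rng):
    """A random parameter set inside the prior support, away from extremes."""
    from treelim.model import ModelParams

    x0 = {"map": rng.uniform(3, 8), "mat": rng.uniform(8, 25),
          "sw": rng.uniform(160, 260), "stress": rng.uniform(0.2, 0.8),
          "human": rng.uniform(0.2, 0.8)}
    k = {"map": rng.uniform(0.2, 3), "mat": rng.uniform(0.05, 0.5),
         "sw": rng.uniform(0.01, 0.1), "stress": rng.uniform(0.5, 8),
         "human": rng.uniform(0.5, 8)}
    weights = {"stress": np.concatenate([[1.0], rng.uniform(0.1, 2.0, 3)]),
               "human": np.concatenate([[1.0], rng.uniform(0.1, 2.0, 3)])}
    exponents = {"stress": rng.uniform(0.3, 2.5, 4), "human": np.ones(4)}
    return ModelParams(x0, k, weights, exponents,
                       tc_max=rng.uniform(0.3, 0.95),
                       sigma=rng.uniform(0.2, 1.0),
                       p0=rng.uniform(0.5, 0.99))
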