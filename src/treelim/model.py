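"""Forward limitation model for fractional tree cover.

Tree cover is the product of logistic limitation factors, one per control:

    TC = TC_max * prod_c f(k_c * (X_c - x0_c)),   f(x) = 1 / (1 + exp(-x))

The five controls are mean annual precipitation (log-transformed), mean
annual temperature, shortwave radiation, a composite environmental stress
index (burnt area, rainfall seasonality, heat, windthrow) and a composite
human-pressure index (population density, urban, cropland, pasture).
Composite control indices are weighted power sums of their factors scaled
to [0, 1]:

    X_c = sum_i v_i * x_i**p_i / sum_i v_i,   v_1 = 1

with exponents free only for the stress control (human-pressure exponents
are fixed to 1).  k is stored as a positive magnitude; suppressive controls
(stress, human) carry sign -1 so their limitation decreases as the index
grows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .grids import DriverSet, GriddedField, FRACTIONAL_DRIVERS

__all__ = [
    "Control",
    "ControlSpec",
    "ModelParams",
    "Predictors",
    "DEFAULT_SCALING",
    "default_control_spec",
    "count_free_parameters",
    "transform_map",
    "scale_factor",
    "control_index",
    "limitation_curve",
    "energy_factor",
    "prepare_predictors",
    "tree_cover",
    "tree_cover_without",
    "tree_cover_field",
]

#: default (min, max) bounds mapping unbounded drivers onto [0, 1]
DEFAULT_SCALING = {
    "mtwm_c": (10.0, 45.0),
    "wind_ms": (0.0, 12.0),
    "pop_density": (0.0, 5000.0),
}


def logistic(x: np.ndarray) -> np.ndarray:
    """Numerically safe standard logistic function."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass(frozen=True)
class Control:
    """One limitation axis.

    ``factors`` is empty for single-driver controls (the driver itself is
    the index) and lists the member driver names for composite controls.
    The first factor is the reference: its weight is fixed to 1.
    """

    name: str
    sign: int  # +1: tree cover increases with the index; -1: suppressive
    driver: str | None = None
    factors: tuple[str, ...] = ()
    exponents_free: bool = False

    @property
    def composite(self) -> bool:
        return len(self.factors) > 0

    @property
    def n_free_weights(self) -> int:
        return max(len(self.factors) - 1, 0)

    @property
    def n_free_exponents(self) -> int:
        return len(self.factors) if self.exponents_free else 0


@dataclass(frozen=True)
class ControlSpec:
    """Ordered controls plus the global parameters the model carries."""

    controls: tuple[Control, ...]
    extra_params: tuple[str, ...] = ("tc_max", "sigma", "p0")

    def control(self, name: str) -> Control:
        for c in self.controls:
            if c.name == name:
                return c
        raise KeyError(f"unknown control {name!r}")

    def owner_of_factor(self, factor: str) -> Control:
        for c in self.controls:
            if factor in c.factors:
                return c
        raise KeyError(f"{factor!r} is not a factor of any composite control")

    def param_names(self) -> list[str]:
        names = []
        for c in self.controls:
            names.append(f"x0_{c.name}")
        for c in self.controls:
            names.append(f"k_{c.name}")
        for c in self.controls:
            for f in c.factors[1:]:
                names.append(f"v_{c.name}_{f}")
            if c.exponents_free:
                for f in c.factors:
                    names.append(f"p_{c.name}_{f}")
        names.extend(self.extra_params)
        return names


def default_control_spec() -> ControlSpec:
    """The standard five-control structure (23 free parameters)."""
    return ControlSpec(
        controls=(
            Control("map", +1, driver="map_mm"),
            Control("mat", +1, driver="mat_c"),
            Control("sw", +1, driver="sw_wm2"),
            Control("stress", -1,
                    factors=("burnt_area", "seasonality", "mtwm_c", "wind_ms"),
                    exponents_free=True),
            Control("human", -1,
                    factors=("pop_density", "urban", "cropland", "pasture")),
        )
    )


def count_free_parameters(spec: ControlSpec) -> int:
    """Number of free model parameters implied by a control structure."""
    n = 0
    for c in spec.controls:
        n += 2  # x0 and k
        n += c.n_free_weights + c.n_free_exponents
    return n + len(spec.extra_params)


@dataclass
class ModelParams:
    """One realisation of the free parameter vector.

    ``k`` holds positive magnitudes; the control's sign supplies the
    direction.  ``weights``/``exponents`` include the fixed entries
    (reference weight 1, unit exponents) so composite indices can be
    evaluated directly.
    """

    x0: dict[str, float]
    k: dict[str, float]
    weights: dict[str, np.ndarray]
    exponents: dict[str, np.ndarray]
    tc_max: float = 0.8
    sigma: float = 0.5
    p0: float = 0.9

    def copy(self) -> "ModelParams":
        return ModelParams(
            dict(self.x0), dict(self.k),
            {k: v.copy() for k, v in self.weights.items()},
            {k: v.copy() for k, v in self.exponents.items()},
            self.tc_max, self.sigma, self.p0,
        )

    def to_vector(self, spec: ControlSpec) -> np.ndarray:
        vals = []
        for c in spec.controls:
            vals.append(self.x0[c.name])
        for c in spec.controls:
            vals.append(self.k[c.name])
        for c in spec.controls:
            if c.composite:
                vals.extend(self.weights[c.name][1:])
            if c.exponents_free:
                vals.extend(self.exponents[c.name])
        for name in spec.extra_params:
            vals.append(getattr(self, name))
        return np.array(vals, dtype=float)

    @classmethod
    def from_vector(cls, vec: np.ndarray, spec: ControlSpec) -> "ModelParams":
        vec = np.asarray(vec, dtype=float)
        if vec.size != count_free_parameters(spec):
            raise ValueError(
                f"expected {count_free_parameters(spec)} parameters, got {vec.size}"
            )
        it = iter(vec)
        x0 = {c.name: next(it) for c in spec.controls}
        k = {c.name: next(it) for c in spec.controls}
        weights, exponents = {}, {}
        for c in spec.controls:
            if c.composite:
                w = np.ones(len(c.factors))
                for i in range(1, len(c.factors)):
                    w[i] = next(it)
                weights[c.name] = w
                p = np.ones(len(c.factors))
                if c.exponents_free:
                    for i in range(len(c.factors)):
                        p[i] = next(it)
                exponents[c.name] = p
        extras = {name: next(it) for name in spec.extra_params}
        return cls(x0, k, weights, exponents, **extras)

    def to_dict(self, spec: ControlSpec) -> dict[str, float]:
        return dict(zip(spec.param_names(), self.to_vector(spec)))


def transform_map(map_mm: np.ndarray, ncells: int) -> np.ndarray:
    """log(MAP + 1/ncells): drives tree cover to zero with vanishing rain.

    ``ncells`` is the number of unmasked analysis cells after clipping to
    the tropical band.
    """
    if ncells <= 0:
        raise ValueError("ncells must be positive")
    map_mm = np.asarray(map_mm, dtype=float)
    if np.any(map_mm < 0):
        raise ValueError("MAP must be non-negative")
    return np.log(map_mm + 1.0 / ncells)


def scale_factor(x: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    """Min-max scale to [0, 1] with clipping; identity for (0, 1) bounds."""
    lo, hi = bounds
    if not hi > lo:
        raise ValueError(f"degenerate scaling bounds {bounds}")
    return np.clip((np.asarray(x, dtype=float) - lo) / (hi - lo), 0.0, 1.0)


def control_index(factors: np.ndarray, weights: np.ndarray,
                  exponents: np.ndarray) -> np.ndarray:
    """Weighted power combination of scaled factors, on [0, 1].

    ``factors`` has shape (n_factors, ...); weights[0] must be 1 and
    exponents positive.
    """
    factors = np.asarray(factors, dtype=float)
    weights = np.asarray(weights, dtype=float)
    exponents = np.asarray(exponents, dtype=float)
    if factors.shape[0] != weights.size or weights.size != exponents.size:
        raise ValueError("factors, weights and exponents lengths must match")
    if not np.isclose(weights[0], 1.0):
        raise ValueError("the reference factor's weight must be fixed to 1")
    if np.any(exponents <= 0):
        raise ValueError("exponents must be positive")
    shaped = weights.reshape((-1,) + (1,) * (factors.ndim - 1))
    num = np.sum(shaped * factors ** exponents.reshape(shaped.shape), axis=0)
    return num / weights.sum()


def limitation_curve(x: np.ndarray, x0: float, k: float) -> np.ndarray:
    """Logistic limitation factor f(k * (X - x0)); 0.5 at the midpoint x0."""
    return logistic(k * (np.asarray(x, dtype=float) - x0))


def energy_factor(mat: np.ndarray, sw: np.ndarray, params: ModelParams) -> np.ndarray:
    """Combined energy limitation: the MAT and SW logistic factors multiplied."""
    return (limitation_curve(mat, params.x0["mat"], params.k["mat"])
            * limitation_curve(sw, params.x0["sw"], params.k["sw"]))


@dataclass
class Predictors:
    """Model-ready predictor arrays over the unmasked analysis cells.

    ``single`` maps single-driver control name to its (transformed) index
    array; ``composite`` maps composite control name to a (n_factors, n)
    matrix of scaled factors.  ``index`` locates each flat cell in the 2-D
    grid for re-embedding.
    """

    single: dict[str, np.ndarray]
    composite: dict[str, np.ndarray]
    mask: np.ndarray
    lat_centers: np.ndarray
    lon_centers: np.ndarray

    @property
    def n_cells(self) -> int:
        return next(iter(self.single.values())).size

    def control_range(self, spec: ControlSpec, name: str) -> tuple[float, float]:
        """Observed (min, max) of a control index at unit weights/exponents."""
        c = spec.control(name)
        if c.composite:
            x = self.composite[name].mean(axis=0)  # indicative; bounded by [0,1]
            return (0.0, 1.0)
        x = self.single[name]
        return (float(x.min()), float(x.max()))

    def subset(self, idx: np.ndarray) -> "Predictors":
        """Restrict to a subset of the flat analysis cells (e.g. a train split).

        The returned mask marks only the selected cells, so ``embed`` still
        places values correctly on the original grid.
        """
        idx = np.asarray(idx)
        rows, cols = np.nonzero(self.mask)
        new_mask = np.zeros_like(self.mask)
        new_mask[rows[idx], cols[idx]] = True
        return Predictors(
            {k: v[idx] for k, v in self.single.items()},
            {k: v[:, idx] for k, v in self.composite.items()},
            new_mask, self.lat_centers, self.lon_centers,
        )

    def embed(self, flat: np.ndarray, name: str = "field",
              units: str = "1") -> GriddedField:
        """Scatter a flat per-cell array back onto the 2-D masked grid."""
        out = np.full(self.mask.shape, np.nan)
        out[self.mask] = flat
        return GriddedField(name, out, self.mask.copy(),
                            self.lat_centers, self.lon_centers, units)


def prepare_predictors(drivers: DriverSet, spec: ControlSpec) -> Predictors:
    """Transform and scale a DriverSet into model-ready per-cell arrays.

    MAP is log-transformed with the 1/ncells floor; composite factors are
    min-max scaled with the bounds recorded on the DriverSet (fractional
    drivers pass through).
    """
    mask = drivers.mask
    ncells = drivers.n_cells
    scaling = {**DEFAULT_SCALING, **drivers.scaling_constants}
    single: dict[str, np.ndarray] = {}
    composite: dict[str, np.ndarray] = {}
    for c in spec.controls:
        if c.composite:
            rows = []
            for fname in c.factors:
                raw = drivers[fname].values[mask]
                bounds = scaling.get(fname, (0.0, 1.0))
                rows.append(raw if bounds == (0.0, 1.0) else scale_factor(raw, bounds))
            composite[c.name] = np.vstack(rows)
        else:
            raw = drivers[c.driver].values[mask]
            if c.driver == "map_mm":
                raw = transform_map(raw, ncells)
            single[c.name] = raw
    lat, lon = drivers.grid
    return Predictors(single, composite, mask.copy(), lat, lon)


def _limitation_factors(pred: Predictors, params: ModelParams, spec: ControlSpec,
                        zero_weight: dict[str, str] | None = None,
                        skip: set[str] | None = None) -> dict[str, np.ndarray]:
    """Per-control logistic factors, optionally zeroing one factor's weight
    or skipping whole controls."""
    skip = skip or set()
    zero_weight = zero_weight or {}
    out = {}
    for c in spec.controls:
        if c.name in skip:
            continue
        if c.composite:
            w = params.weights[c.name]
            if c.name in zero_weight:
                w = w.copy()
                idx = c.factors.index(zero_weight[c.name])
                w[idx] = 0.0
                if idx == 0:
                    # the reference weight is fixed at 1 by convention; when the
                    # reference factor itself is removed, renormalise over the rest
                    if w[1:].sum() > 0:
                        x = np.sum(
                            w[1:, None] * pred.composite[c.name][1:]
                            ** params.exponents[c.name][1:, None], axis=0
                        ) / w[1:].sum()
                    else:
                        x = np.zeros(pred.n_cells)
                    out[c.name] = logistic(c.sign * params.k[c.name] * (x - params.x0[c.name]))
                    continue
            if w.sum() > 0:
                x = np.sum(
                    w[:, None] * pred.composite[c.name] ** params.exponents[c.name][:, None],
                    axis=0,
                ) / w.sum()
            else:
                x = np.zeros(pred.n_cells)
        else:
            x = pred.single[c.name]
        out[c.name] = logistic(c.sign * params.k[c.name] * (x - params.x0[c.name]))
    return out


def tree_cover(pred: Predictors, params: ModelParams, spec: ControlSpec) -> np.ndarray:
    """Predicted fractional tree cover on the unmasked cells."""
    tc = np.full(pred.n_cells, params.tc_max)
    for f in _limitation_factors(pred, params, spec).values():
        tc = tc * f
    return tc


def tree_cover_without(pred: Predictors, params: ModelParams, spec: ControlSpec,
                       removed: str | Sequence[str]) -> np.ndarray:
    """Tree cover with one or more controls/factors removed.

    Removing a control drops its logistic from the product; removing a
    factor of a composite control recomputes that control's index with the
    factor's weight set to zero (the weighted-sum denominator renormalises).
    """
    removed_list = [removed] if isinstance(removed, str) else list(removed)
    skip: set[str] = set()
    zero_weight: dict[str, str] = {}
    control_names = {c.name for c in spec.controls}
    for r in removed_list:
        if r in control_names:
            skip.add(r)
        else:
            owner = spec.owner_of_factor(r)  # KeyError for unknown ids
            zero_weight[owner.name] = r
    tc = np.full(pred.n_cells, params.tc_max)
    for f in _limitation_factors(pred, params, spec, zero_weight, skip).values():
        tc = tc * f
    return tc


def tree_cover_field(drivers: DriverSet, params: ModelParams,
                     spec: ControlSpec) -> GriddedField:
    """Convenience wrapper returning predicted cover as a GriddedField."""
    pred = prepare_predictors(drivers, spec)
    return pred.embed(tree_cover(pred, params, spec), name="tree_cover", units="1")
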