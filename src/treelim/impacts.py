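"""Impact calculus on fitted limitation models.

Measures of how much each control or factor suppresses tree cover:

* absolute impact  |TC_*(i) - TC|, the cover difference with and without i;
* relative impact  (TC_*(i) - TC) / TC_*(i), the fraction of the cover the
  factor would otherwise allow;
* limitation       1 - f for climate controls, normalised for suppressive
  controls so zero stress means zero limitation;
* sensitivity      the logistic gradient relative to its midpoint maximum,
  times the cover unconstrained by that control;
* counterfactual fire experiments (+1% burnt area; fire without direct human
  influence on tree cover; fire with a reconstructed no-human burnt area);
* per-unit response curves in 1% factor bins;
* Bhattacharyya overlap between impact distributions of two factors.

Uncertainty always propagates by evaluating each posterior member and
pairing members across experiments, never by independent resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import DriverSet
from .inference import PosteriorEnsemble
from .model import (
    ControlSpec,
    ModelParams,
    Predictors,
    limitation_curve,
    logistic,
    prepare_predictors,
    tree_cover,
    tree_cover_without,
)

__all__ = [
    "ImpactDistribution",
    "absolute_impact",
    "relative_impact",
    "ensemble_impact",
    "bhattacharyya",
    "pairwise_difference_probability",
    "limitation",
    "sensitivity",
    "fire_increment_experiment",
    "fire_without_humans",
    "fire_without_humans_and_ba",
    "response_curve",
    "quantile_summary",
]


@dataclass
class ImpactDistribution:
    """Per-cell impact values across posterior members.

    ``values`` has shape (n_members, n_cells); NaN marks cells where the
    measure is undefined (e.g. relative impact with zero unconstrained
    cover).
    """

    values: np.ndarray
    kind: str = "relative"
    target: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))

    @property
    def n_members(self) -> int:
        return self.values.shape[0]

    def quantile(self, levels) -> np.ndarray:
        """Per-cell empirical quantiles across members (linear interpolation)."""
        return np.nanquantile(self.values, levels, axis=0)

    def pooled(self) -> np.ndarray:
        """All finite values flattened, for distribution-level comparisons."""
        v = self.values.ravel()
        return v[np.isfinite(v)]


def _signed_k(spec: ControlSpec, params: ModelParams, name: str) -> float:
    return spec.control(name).sign * params.k[name]


def _control_factor(pred: Predictors, params: ModelParams, spec: ControlSpec,
                    control: str) -> np.ndarray:
    """The logistic limitation factor of one control."""
    c = spec.control(control)
    if c.composite:
        from .model import control_index

        x = control_index(pred.composite[control], params.weights[control],
                          params.exponents[control])
    else:
        x = pred.single[control]
    return limitation_curve(x, params.x0[control], _signed_k(spec, params, control))


def absolute_impact(pred: Predictors, params: ModelParams, spec: ControlSpec,
                    target: str) -> np.ndarray:
    """|TC_*(target) - TC| per cell."""
    tc = tree_cover(pred, params, spec)
    tc_star = tree_cover_without(pred, params, spec, target)
    return np.abs(tc_star - tc)


def relative_impact(pred: Predictors, params: ModelParams, spec: ControlSpec,
                    target: str, printed_form: bool = False) -> np.ndarray:
    """(TC_*(target) - TC) / TC_*(target) per cell.

    Cells where the unconstrained cover is zero are NaN.  ``printed_form``
    switches to the alternative TC * (1 - f) expression for whole controls,
    kept for comparison only.
    """
    tc = tree_cover(pred, params, spec)
    if printed_form:
        f = _control_factor(pred, params, spec, target)
        return tc * (1.0 - f)
    tc_star = tree_cover_without(pred, params, spec, target)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(tc_star > 0, (tc_star - tc) / np.where(tc_star > 0, tc_star, 1.0),
                       np.nan)
    return out


def ensemble_impact(pred: Predictors, ensemble: PosteriorEnsemble,
                    spec: ControlSpec, target: str,
                    kind: str = "relative") -> ImpactDistribution:
    """Impact of one target evaluated for every posterior member."""
    fn = {"relative": relative_impact, "absolute": absolute_impact}[kind]
    vals = np.stack([fn(pred, ensemble.member(i), spec, target)
                     for i in range(len(ensemble))])
    return ImpactDistribution(vals, kind=kind, target=target)


def bhattacharyya(p: np.ndarray, q: np.ndarray) -> float:
    """Bhattacharyya coefficient of two discrete probability vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("probability vectors must share a binning")
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValueError("probability vectors must have positive mass")
    return float(np.sum(np.sqrt((p / p.sum()) * (q / q.sum()))))


def pairwise_difference_probability(d_i: ImpactDistribution, d_j: ImpactDistribution,
                                    n_bins: int = 100,
                                    support: tuple[float, float] = (0.0, 1.0)) -> float:
    """Overlap of two impact distributions on a shared histogram binning.

    Returns the Bhattacharyya coefficient in [0, 1]: 1 for identical
    distributions, 0 for disjoint ones.  The headline convention reports
    1 minus this overlap as the probability that the impacts differ.
    """
    vi, vj = d_i.pooled(), d_j.pooled()
    if vi.size == 0 or vj.size == 0:
        raise ValueError("impact distributions are empty")
    edges = np.linspace(support[0], support[1], n_bins + 1)
    hi, _ = np.histogram(np.clip(vi, *support), bins=edges)
    hj, _ = np.histogram(np.clip(vj, *support), bins=edges)
    return bhattacharyya(hi, hj)


def limitation(pred: Predictors, params: ModelParams, spec: ControlSpec,
               control: str) -> np.ndarray:
    """One minus the maximum cover a control allows, per cell.

    For suppressive controls the factor is first normalised by its value at
    zero stress, so no stress (or no human pressure) means no limitation.
    """
    c = spec.control(control)
    f = _control_factor(pred, params, spec, control)
    if c.sign > 0:
        return 1.0 - f
    f_at_zero = logistic(np.array([c.sign * params.k[control] * (0.0 - params.x0[control])]))[0]
    return 1.0 - f / f_at_zero


def sensitivity(pred: Predictors, params: ModelParams, spec: ControlSpec,
                target: str) -> np.ndarray:
    """Normalised responsiveness of cover to a control.

    G = f'(k(X - x0)) / f'(0) = 4 f (1 - f) is the logistic gradient scaled
    by its midpoint maximum; the sensitivity is G times the cover
    unconstrained by the target, so it lies in [0, TC_*].
    """
    f = _control_factor(pred, params, spec, target)
    g = 4.0 * f * (1.0 - f)
    return g * tree_cover_without(pred, params, spec, target)


def _with_burnt_area(pred: Predictors, spec: ControlSpec,
                     burnt: np.ndarray) -> Predictors:
    """Predictors with the stress control's burnt-area row replaced."""
    owner = spec.owner_of_factor("burnt_area")
    row = owner.factors.index("burnt_area")
    comp = {k: v.copy() for k, v in pred.composite.items()}
    comp[owner.name][row] = burnt
    return Predictors(dict(pred.single), comp, pred.mask,
                      pred.lat_centers, pred.lon_centers)


def fire_increment_experiment(pred: Predictors, ensemble: PosteriorEnsemble,
                              spec: ControlSpec, delta: float = 0.01) -> ImpactDistribution:
    """Tree-cover loss from a uniform burnt-area increase (default +1%).

    Per member, TC(burnt) - TC(burnt + delta), paired against the standard
    run so parameter co-variation cancels.
    """
    owner = spec.owner_of_factor("burnt_area")
    row = owner.factors.index("burnt_area")
    burnt = pred.composite[owner.name][row]
    pred_up = _with_burnt_area(pred, spec, np.clip(burnt + delta, 0.0, 1.0))
    vals = np.empty((len(ensemble), pred.n_cells))
    for i in range(len(ensemble)):
        m = ensemble.member(i)
        vals[i] = tree_cover(pred, m, spec) - tree_cover(pred_up, m, spec)
    return ImpactDistribution(vals, kind="absolute", target="burnt_area+1%")


def _fire_no_human_member(pred: Predictors, params: ModelParams, spec: ControlSpec,
                          kind: str) -> np.ndarray:
    tc_no_lu_ba = tree_cover_without(pred, params, spec, ["burnt_area", "human"])
    tc_no_lu = tree_cover_without(pred, params, spec, "human")
    if kind == "absolute":
        return np.abs(tc_no_lu_ba - tc_no_lu)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tc_no_lu_ba > 0,
                        (tc_no_lu_ba - tc_no_lu) / np.where(tc_no_lu_ba > 0, tc_no_lu_ba, 1.0),
                        np.nan)


def fire_without_humans(pred: Predictors, ensemble: PosteriorEnsemble,
                        spec: ControlSpec, kind: str = "relative") -> ImpactDistribution:
    """Fire impact with direct human influence on tree cover removed.

    Compares cover without human pressure against cover without human
    pressure and burnt area: (TC_*(BA, LU) - TC_*(LU)) / TC_*(BA, LU).
    When human pressure is nowhere limiting this reduces to the standard
    fire impact.
    """
    vals = np.stack([
        _fire_no_human_member(pred, ensemble.member(i), spec, kind)
        for i in range(len(ensemble))
    ])
    return ImpactDistribution(vals, kind=kind, target="burnt_area|no-human")


def fire_without_humans_and_ba(pred: Predictors, ensemble: PosteriorEnsemble,
                               spec: ControlSpec, ba_counterfactual: np.ndarray,
                               seed: int = 0, kind: str = "relative") -> ImpactDistribution:
    """As :func:`fire_without_humans`, with burnt area itself replaced.

    ``ba_counterfactual`` is an (n_fields, n_cells) ensemble of
    reconstructed burnt-area fields without human influence; each posterior
    member is paired with one randomly sampled counterfactual field.
    """
    ba = np.atleast_2d(np.asarray(ba_counterfactual, dtype=float))
    if ba.shape[1] != pred.n_cells:
        raise ValueError("counterfactual burnt-area fields are not on the analysis grid")
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, ba.shape[0], size=len(ensemble))
    vals = np.empty((len(ensemble), pred.n_cells))
    for i in range(len(ensemble)):
        pred_cf = _with_burnt_area(pred, spec, ba[pick[i]])
        vals[i] = _fire_no_human_member(pred_cf, ensemble.member(i), spec, kind)
    return ImpactDistribution(vals, kind=kind, target="burnt_area|no-human-ba")


def response_curve(pred: Predictors, ensemble: PosteriorEnsemble, spec: ControlSpec,
                   factor: str, bin_width: float = 0.01) -> dict[str, np.ndarray]:
    """Per-unit tree-cover exclusion in factor-level bins.

    Cells are grouped into bins of the (area-fraction) factor; within a
    bin the response is (TC_*(i) - TC) / (A_bin * TC_*(i)) with A_bin the
    bin's factor level, so 1 means the factor excludes tree cover over
    exactly its own area.  Returns bin centres, occupancy, and the median
    and 10-90% member percentiles of the cell-averaged response; empty
    bins are dropped.
    """
    owner = spec.owner_of_factor(factor)
    row = owner.factors.index(factor)
    levels = pred.composite[owner.name][row]
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    which = np.clip(np.digitize(levels, edges) - 1, 0, edges.size - 2)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.bincount(which, minlength=centers.size)

    rel = np.stack([relative_impact(pred, ensemble.member(i), spec, factor)
                    for i in range(len(ensemble))])
    per_bin = []
    keep = []
    for b in range(centers.size):
        cells = which == b
        if counts[b] == 0 or centers[b] <= 0:
            continue
        with np.errstate(invalid="ignore"):
            resp = np.nanmean(rel[:, cells], axis=1) / centers[b]
        per_bin.append(resp)
        keep.append(b)
    keep = np.array(keep, dtype=int)
    per_bin = np.array(per_bin)  # (n_kept_bins, n_members)
    return {
        "bin_center": centers[keep],
        "count": counts[keep],
        "median": np.nanmedian(per_bin, axis=1),
        "q10": np.nanquantile(per_bin, 0.10, axis=1),
        "q90": np.nanquantile(per_bin, 0.90, axis=1),
    }


def quantile_summary(dist: ImpactDistribution,
                     levels: tuple[float, ...] = (0.10, 0.90)) -> np.ndarray:
    """Per-cell quantile bounds of an impact distribution.

    The default is the 10-90% band; passing (0.35, 0.65) gives the
    asymmetric convention used for dominant-control maps.
    """
    if dist.n_members < 2:
        raise ValueError("need at least two members for quantile bounds")
    return dist.quantile(levels)


def impact_fields(drivers: DriverSet, ensemble: PosteriorEnsemble, spec: ControlSpec,
                  target: str, kind: str = "relative",
                  levels: tuple[float, float] = (0.10, 0.90)):
    """Quantile-bound impact maps for one target, as GriddedFields."""
    pred = prepare_predictors(drivers, spec)
    dist = ensemble_impact(pred, ensemble, spec, target, kind)
    lo, hi = quantile_summary(dist, levels)
    return (pred.embed(lo, f"{kind}_impact_{target}_q{int(levels[0]*100)}"),
            pred.embed(hi, f"{kind}_impact_{target}_q{int(levels[1]*100)}"))
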