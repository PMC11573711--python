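"""Biome grouping and Table-style aggregation of impacts.

Olson ecoregion classes are grouped into seven coarse tropical biomes (wet
forest, dry forest, savanna/grassland, mediterranean, summergreen
forest/woodland, desert, other).  Impacts aggregate per biome as
cos(latitude)-area-weighted sums, evaluated for each posterior member first
and quantiled across members afterwards, so the reported bounds reflect
framework (parameter) uncertainty rather than cell-to-cell spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .impacts import ImpactDistribution
from .inference import PosteriorEnsemble
from .model import ControlSpec, Predictors, tree_cover, tree_cover_without

__all__ = [
    "GROUP_NAMES",
    "OLSON_GROUPING",
    "BiomeMap",
    "group_olson_codes",
    "aggregate_by_biome",
    "biome_impact_table",
    "tree_cover_histogram",
    "ensemble_histogram",
]

#: coarse biome groups, index = group code
GROUP_NAMES = (
    "wet_forest",
    "dry_forest",
    "savanna_grassland",
    "mediterranean",
    "summergreen",
    "desert",
    "other",
)

#: default grouping of Olson biome codes (1-14) into the coarse groups;
#: editable data, not behaviour — residual classes map to "other"
OLSON_GROUPING = {
    1: "wet_forest",        # tropical & subtropical moist broadleaf forest
    2: "dry_forest",        # tropical & subtropical dry broadleaf forest
    3: "wet_forest",        # tropical & subtropical coniferous forest
    4: "summergreen",       # temperate broadleaf & mixed forest
    5: "summergreen",       # temperate conifer forest
    7: "savanna_grassland", # tropical & subtropical grasslands/savannas/shrublands
    8: "summergreen",       # temperate grasslands, savannas & shrublands
    12: "mediterranean",    # mediterranean forests, woodlands & scrub
    13: "desert",           # deserts & xeric shrublands
}


@dataclass
class BiomeMap:
    """Per-cell coarse biome codes over the unmasked analysis cells."""

    codes: np.ndarray
    group_names: tuple[str, ...] = GROUP_NAMES

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int).ravel()
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() >= len(self.group_names)):
            raise ValueError("biome codes outside the group table")

    @property
    def n(self) -> int:
        return self.codes.size

    def cells_in(self, group: str) -> np.ndarray:
        return self.codes == self.group_names.index(group)

    def present_groups(self) -> list[str]:
        return [g for i, g in enumerate(self.group_names) if np.any(self.codes == i)]


def group_olson_codes(olson: np.ndarray,
                      grouping: dict[int, str] = OLSON_GROUPING) -> BiomeMap:
    """Map raw Olson class codes onto the coarse biome groups.

    Codes absent from the grouping table fall into "other".
    """
    olson = np.asarray(olson, dtype=int).ravel()
    out = np.full(olson.shape, GROUP_NAMES.index("other"), dtype=int)
    for code, group in grouping.items():
        out[olson == code] = GROUP_NAMES.index(group)
    return BiomeMap(out)


def aggregate_by_biome(abs_impact: ImpactDistribution, unconstrained: np.ndarray,
                       biomes: BiomeMap, weights: np.ndarray,
                       deciduous: np.ndarray | None = None,
                       levels: tuple[float, float] = (0.10, 0.90)) -> pd.DataFrame:
    """Area and relative impact per biome with member-quantile bounds.

    ``abs_impact`` holds |TC_* - TC| per member and cell; ``unconstrained``
    the matching TC_* values.  Per member and biome the area impact is the
    area-weighted sum of the absolute impact (cell-area units) and the
    relative impact is that sum over the area-weighted unconstrained cover,
    in percent.  Quantiles are taken across members afterwards.  A
    ``deciduous`` fraction multiplies the area weights when given.
    """
    vals = abs_impact.values
    tc_star = np.atleast_2d(np.asarray(unconstrained, dtype=float))
    w = np.asarray(weights, dtype=float).ravel()
    if deciduous is not None:
        w = w * np.asarray(deciduous, dtype=float).ravel()
    if vals.shape != tc_star.shape or vals.shape[1] != w.size or w.size != biomes.n:
        raise ValueError("impact, unconstrained cover, weights and biomes must align")
    rows = []
    for group in biomes.present_groups():
        cells = biomes.cells_in(group)
        area = np.nansum(vals[:, cells] * w[cells], axis=1)
        denom = np.nansum(tc_star[:, cells] * w[cells], axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(denom > 0, 100.0 * area / np.where(denom > 0, denom, 1.0), np.nan)
        rows.append({
            "biome": group,
            "target": abs_impact.target,
            "area_q10": float(np.quantile(area, levels[0])),
            "area_q90": float(np.quantile(area, levels[1])),
            "relative_pct_q10": float(np.nanquantile(rel, levels[0])),
            "relative_pct_q90": float(np.nanquantile(rel, levels[1])),
        })
    return pd.DataFrame(rows)


def biome_impact_table(pred: Predictors, ensemble: PosteriorEnsemble, spec: ControlSpec,
                       targets: list[str], biomes: BiomeMap, weights: np.ndarray,
                       deciduous: np.ndarray | None = None,
                       levels: tuple[float, float] = (0.10, 0.90)) -> pd.DataFrame:
    """Table-1-shaped summary: biome x target impact with quantile bounds."""
    frames = []
    for target in targets:
        vals = np.empty((len(ensemble), pred.n_cells))
        star = np.empty_like(vals)
        for i in range(len(ensemble)):
            m = ensemble.member(i)
            tc = tree_cover(pred, m, spec)
            ts = tree_cover_without(pred, m, spec, target)
            vals[i] = np.abs(ts - tc)
            star[i] = ts
        dist = ImpactDistribution(vals, kind="absolute", target=target)
        frames.append(aggregate_by_biome(dist, star, biomes, weights, deciduous, levels))
    return pd.concat(frames, ignore_index=True)


def tree_cover_histogram(tc: np.ndarray, bin_width: float = 0.01,
                         by: BiomeMap | None = None):
    """Counts of tree cover in fixed-width bins, optionally split by biome.

    Returns (edges, counts) or, with ``by``, (edges, {group: counts}).
    Counts always sum to the number of cells supplied.
    """
    tc = np.asarray(tc, dtype=float).ravel()
    if np.any((tc < 0) | (tc > 1)):
        raise ValueError("tree cover must lie in [0, 1]")
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    if by is None:
        counts, _ = np.histogram(tc, bins=edges)
        return edges, counts
    stacked = {}
    for group in by.present_groups():
        counts, _ = np.histogram(tc[by.cells_in(group)], bins=edges)
        stacked[group] = counts
    return edges, stacked


def ensemble_histogram(tc_members: np.ndarray, bin_width: float = 0.01,
                       levels: tuple[float, float] = (0.10, 0.90)):
    """Per-member tree-cover histograms with a quantile envelope.

    ``tc_members`` has shape (n_members, n_cells); returns (edges, lo, hi)
    where lo/hi are the per-bin member quantiles of the counts.
    """
    tc_members = np.atleast_2d(tc_members)
    edges = None
    counts = []
    for row in tc_members:
        edges, c = tree_cover_histogram(row, bin_width)
        counts.append(c)
    counts = np.stack(counts)
    lo, hi = np.quantile(counts, levels, axis=0)
    return edges, lo, hi
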