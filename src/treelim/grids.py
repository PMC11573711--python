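"""Gridded data model and NetCDF plumbing for the limitation pipeline.

Everything downstream operates on :class:`GriddedField` objects: one named
variable on a regular latitude/longitude grid with an explicit validity mask
and units.  The analysis convention is cell-centre coordinates at 0.5 degree
spacing, with the tropical band spanning centres -29.75..29.75 in latitude
and -179.75..179.75 in longitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import xarray as xr

__all__ = [
    "GriddedField",
    "DriverSet",
    "DRIVER_NAMES",
    "tropics_grid",
    "read_netcdf",
    "write_netcdf",
    "read_driverset",
    "write_driverset",
    "clip_to_tropics",
    "regrid_bilinear",
    "cell_area_weights",
    "area_weighted_mean",
]

#: canonical names of the 11 predictor fields, in pipeline order
DRIVER_NAMES = (
    "map_mm",
    "mat_c",
    "sw_wm2",
    "burnt_area",
    "seasonality",
    "mtwm_c",
    "wind_ms",
    "pop_density",
    "urban",
    "cropland",
    "pasture",
)

#: drivers that are already fractions on [0, 1] and pass through unscaled
FRACTIONAL_DRIVERS = frozenset({"burnt_area", "seasonality", "urban", "cropland", "pasture"})


class GridError(ValueError):
    """Raised for unsupported or incompatible grids."""


class EmptyDomainError(GridError):
    """Raised when an operation leaves no cells in the requested domain."""


def _check_regular(coords: np.ndarray, axis_name: str) -> float:
    if coords.ndim != 1 or coords.size < 1:
        raise GridError(f"{axis_name} coordinates must be a 1-D array")
    if coords.size == 1:
        return np.nan
    steps = np.diff(coords)
    if np.any(steps <= 0):
        raise GridError(f"{axis_name} coordinates must be strictly increasing")
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise GridError(f"{axis_name} spacing is irregular; only regular grids are supported")
    return float(steps[0])


@dataclass(frozen=True)
class GriddedField:
    """One variable on a regular lat-lon grid.

    ``mask`` is True on valid cells.  Values on masked cells are never used
    in any computation; they are written as NaN on output.
    """

    name: str
    values: np.ndarray
    mask: np.ndarray
    lat_centers: np.ndarray
    lon_centers: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        lat = np.asarray(self.lat_centers, dtype=float)
        lon = np.asarray(self.lon_centers, dtype=float)
        if values.shape != (lat.size, lon.size):
            raise GridError(
                f"values shape {values.shape} does not match grid ({lat.size}, {lon.size})"
            )
        if mask.shape != values.shape:
            raise GridError("mask shape must match values shape")
        _check_regular(lat, "lat")
        _check_regular(lon, "lon")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "lat_centers", lat)
        object.__setattr__(self, "lon_centers", lon)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_grid(self, other: "GriddedField") -> bool:
        return (
            self.lat_centers.shape == other.lat_centers.shape
            and self.lon_centers.shape == other.lon_centers.shape
            and np.allclose(self.lat_centers, other.lat_centers)
            and np.allclose(self.lon_centers, other.lon_centers)
        )

    def valid_values(self) -> np.ndarray:
        """Values on unmasked cells, as a flat array."""
        return self.values[self.mask]

    def with_values(self, values: np.ndarray, name: str | None = None,
                    units: str | None = None) -> "GriddedField":
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            name=self.name if name is None else name,
            units=self.units if units is None else units,
        )


def tropics_grid(resolution: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Cell-centre coordinates for the 30N-30S analysis band.

    First latitude centre sits at -(30 - resolution/2); longitudes cover the
    full circle.
    """
    half = resolution / 2.0
    lat = np.arange(-30.0 + half, 30.0, resolution)
    lon = np.arange(-180.0 + half, 180.0, resolution)
    return lat, lon


@dataclass
class DriverSet:
    """The 11 predictor fields plus per-factor scaling metadata.

    ``scaling_constants`` maps driver name to the (min, max) bounds used to
    map unbounded factors onto [0, 1] before they enter a control index;
    fraction-valued drivers carry (0, 1) and pass through unchanged.  The
    bounds travel with the data so fitted parameters stay interpretable.
    """

    fields: dict[str, GriddedField]
    scaling_constants: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [n for n in DRIVER_NAMES if n not in self.fields]
        if missing:
            raise ValueError(f"DriverSet is missing predictor fields: {missing}")
        ref = self.fields[DRIVER_NAMES[0]]
        for name in DRIVER_NAMES:
            f = self.fields[name]
            if not f.same_grid(ref):
                raise GridError(f"driver {name!r} is not on the shared grid")
            if not np.array_equal(f.mask, ref.mask):
                raise GridError(f"driver {name!r} does not share the common mask")
        for name in FRACTIONAL_DRIVERS:
            vals = self.fields[name].valid_values()
            if vals.size and (vals.min() < -1e-9 or vals.max() > 1 + 1e-9):
                raise ValueError(f"fractional driver {name!r} has values outside [0, 1]")
            self.scaling_constants.setdefault(name, (0.0, 1.0))

    def __getitem__(self, name: str) -> GriddedField:
        return self.fields[name]

    @property
    def mask(self) -> np.ndarray:
        return self.fields[DRIVER_NAMES[0]].mask

    @property
    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        f = self.fields[DRIVER_NAMES[0]]
        return f.lat_centers, f.lon_centers

    @property
    def n_cells(self) -> int:
        """Number of unmasked analysis cells."""
        return int(self.mask.sum())

    def replace_field(self, name: str, values: np.ndarray) -> "DriverSet":
        """A copy of the set with one driver's values replaced."""
        new_fields = dict(self.fields)
        new_fields[name] = self.fields[name].with_values(values)
        return DriverSet(new_fields, dict(self.scaling_constants))


def read_netcdf(path, varname: str) -> GriddedField:
    """Read one variable from a NetCDF file as a :class:`GriddedField`.

    A 3-D variable with a leading time axis is averaged over time.  The mask
    comes from the file's missing-value convention (NaN after decoding).
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        if varname not in ds:
            raise KeyError(f"variable {varname!r} not found in {path}")
        da = ds[varname]
        dims = list(da.dims)
        if "time" in dims:
            da = da.mean(dim="time")
            dims = list(da.dims)
        if len(dims) != 2:
            raise GridError(f"variable {varname!r} is not 2-D after time averaging")
        lat_name = "lat" if "lat" in dims else dims[0]
        lon_name = "lon" if "lon" in dims else dims[1]
        da = da.transpose(lat_name, lon_name)
        lat = np.asarray(da[lat_name].values, dtype=float)
        lon = np.asarray(da[lon_name].values, dtype=float)
        if lat.size > 1 and lat[0] > lat[-1]:
            da = da.isel({lat_name: slice(None, None, -1)})
            lat = lat[::-1]
        values = np.asarray(da.values, dtype=float)
        units = str(da.attrs.get("units", ""))
    mask = np.isfinite(values)
    return GriddedField(varname, np.where(mask, values, np.nan), mask, lat, lon, units)


def write_netcdf(field_obj: GriddedField, path, attrs: Mapping[str, str] | None = None) -> None:
    """Write a field with CF-style coordinates; masked cells become NaN."""
    values = np.where(field_obj.mask, field_obj.values, np.nan)
    da = xr.DataArray(
        values,
        dims=("lat", "lon"),
        coords={"lat": field_obj.lat_centers, "lon": field_obj.lon_centers},
        name=field_obj.name,
        attrs={"units": field_obj.units, "_FillValue": np.nan},
    )
    da["lat"].attrs["units"] = "degrees_north"
    da["lon"].attrs["units"] = "degrees_east"
    ds = da.to_dataset()
    if attrs:
        ds.attrs.update(attrs)
    ds.to_netcdf(path, engine="scipy")


def write_driverset(drivers: DriverSet, path, attrs: Mapping[str, str] | None = None) -> None:
    """Write all 11 predictor fields to one NetCDF file.

    Per-factor scaling bounds are stored as variable attributes so fitted
    parameters stay interpretable after a round trip.
    """
    data_vars = {}
    ref = drivers.fields[DRIVER_NAMES[0]]
    for name in DRIVER_NAMES:
        f = drivers.fields[name]
        lo, hi = drivers.scaling_constants.get(name, (0.0, 1.0))
        data_vars[name] = xr.DataArray(
            np.where(f.mask, f.values, np.nan), dims=("lat", "lon"),
            attrs={"units": f.units, "scale_min": lo, "scale_max": hi,
                   "_FillValue": np.nan},
        )
    ds = xr.Dataset(data_vars, coords={"lat": ref.lat_centers, "lon": ref.lon_centers})
    if attrs:
        ds.attrs.update(attrs)
    ds.to_netcdf(path, engine="scipy")


def read_driverset(path) -> DriverSet:
    """Read a DriverSet written by :func:`write_driverset`."""
    with xr.open_dataset(path, engine="scipy") as ds:
        lat = np.asarray(ds["lat"].values, dtype=float)
        lon = np.asarray(ds["lon"].values, dtype=float)
        fields = {}
        scaling = {}
        for name in DRIVER_NAMES:
            if name not in ds:
                raise KeyError(f"driver {name!r} missing from {path}")
            values = np.asarray(ds[name].values, dtype=float)
            mask = np.isfinite(values)
            fields[name] = GriddedField(name, values, mask, lat, lon,
                                        str(ds[name].attrs.get("units", "")))
            if "scale_min" in ds[name].attrs:
                scaling[name] = (float(ds[name].attrs["scale_min"]),
                                 float(ds[name].attrs["scale_max"]))
    return DriverSet(fields, scaling)


def clip_to_tropics(field_obj: GriddedField, south: float = -30.0,
                    north: float = 30.0) -> GriddedField:
    """Retain only cells whose latitude centres fall inside [south, north]."""
    keep = (field_obj.lat_centers >= south) & (field_obj.lat_centers <= north)
    if not keep.any():
        raise EmptyDomainError(
            f"no latitude centres inside [{south}, {north}]"
        )
    return replace(
        field_obj,
        values=field_obj.values[keep, :],
        mask=field_obj.mask[keep, :],
        lat_centers=field_obj.lat_centers[keep],
    )


def _axis_weights(src: np.ndarray, tgt: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bracketing indices and linear weight for 1-D interpolation.

    Target points outside the source range clamp to the edge cell.
    """
    idx1 = np.searchsorted(src, tgt, side="right")
    idx1 = np.clip(idx1, 1, src.size - 1) if src.size > 1 else np.zeros_like(idx1)
    idx0 = idx1 - 1 if src.size > 1 else idx1
    if src.size > 1:
        w1 = (tgt - src[idx0]) / (src[idx1] - src[idx0])
        w1 = np.clip(w1, 0.0, 1.0)
    else:
        w1 = np.zeros(tgt.shape)
    return idx0, idx1, w1


def regrid_bilinear(field_obj: GriddedField, target_lat: np.ndarray,
                    target_lon: np.ndarray) -> GriddedField:
    """Bilinear interpolation from source cell centres to a target grid.

    A target cell is masked only when all four bracketing source cells are
    masked; otherwise masked neighbours are dropped and the remaining
    bilinear weights renormalised, which preserves coastal coverage.
    """
    target_lat = np.asarray(target_lat, dtype=float)
    target_lon = np.asarray(target_lon, dtype=float)
    _check_regular(target_lat, "target lat")
    _check_regular(target_lon, "target lon")
    src_lat, src_lon = field_obj.lat_centers, field_obj.lon_centers
    if target_lat.max() < src_lat.min() - 1e-9 or target_lat.min() > src_lat.max() + 1e-9:
        raise EmptyDomainError("target grid does not overlap the source in latitude")
    if target_lon.max() < src_lon.min() - 1e-9 or target_lon.min() > src_lon.max() + 1e-9:
        raise EmptyDomainError("target grid does not overlap the source in longitude")

    i0, i1, wy = _axis_weights(src_lat, target_lat)
    j0, j1, wx = _axis_weights(src_lon, target_lon)

    vals = np.where(field_obj.mask, field_obj.values, 0.0)
    ok = field_obj.mask.astype(float)

    wy0, wy1 = (1.0 - wy)[:, None], wy[:, None]
    wx0, wx1 = (1.0 - wx)[None, :], wx[None, :]

    def corner(v, ii, jj):
        return v[np.ix_(ii, jj)]

    num = (
        corner(vals, i0, j0) * corner(ok, i0, j0) * wy0 * wx0
        + corner(vals, i0, j1) * corner(ok, i0, j1) * wy0 * wx1
        + corner(vals, i1, j0) * corner(ok, i1, j0) * wy1 * wx0
        + corner(vals, i1, j1) * corner(ok, i1, j1) * wy1 * wx1
    )
    den = (
        corner(ok, i0, j0) * wy0 * wx0
        + corner(ok, i0, j1) * wy0 * wx1
        + corner(ok, i1, j0) * wy1 * wx0
        + corner(ok, i1, j1) * wy1 * wx1
    )
    any_valid = (
        corner(ok, i0, j0) + corner(ok, i0, j1) + corner(ok, i1, j0) + corner(ok, i1, j1)
    ) > 0
    out_mask = any_valid & (den > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(out_mask, num / np.where(den > 0, den, 1.0), np.nan)
    return GriddedField(field_obj.name, out, out_mask, target_lat, target_lon, field_obj.units)


def cell_area_weights(lat_centers: np.ndarray, lon_centers: np.ndarray) -> GriddedField:
    """Per-cell area weight proportional to cos(latitude).

    Normalised so an equatorial cell has weight exactly 1; the constant
    cancels in any weighted mean.
    """
    lat = np.asarray(lat_centers, dtype=float)
    lon = np.asarray(lon_centers, dtype=float)
    w = np.cos(np.deg2rad(lat))[:, None] * np.ones((1, lon.size))
    return GriddedField("cell_area_weight", w, np.ones_like(w, bool), lat, lon, "1")


def area_weighted_mean(field_obj: GriddedField) -> float:
    """cos(lat)-weighted mean over unmasked cells."""
    w = cell_area_weights(field_obj.lat_centers, field_obj.lon_centers).values
    m = field_obj.mask
    return float(np.sum(field_obj.values[m] * w[m]) / np.sum(w[m]))
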