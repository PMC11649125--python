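"""Gridded time-series containers and raster I/O.

The pipeline's universal currency is the :class:`GridStack`: a
``(time, rows, cols)`` cube of one physical variable with an explicit
missing-value mask, units and an affine georeference.  Categorical
grassland-type rasters are carried by :class:`TypeMap`.

NetCDF I/O goes through xarray (scipy backend, NetCDF-3 classic);
categorical/flag rasters are written as plain TIFF with a CSV sidecar
carrying the legend and the affine parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr


@dataclass(frozen=True)
class GridGeo:
    """Affine georeference of a regular lon/lat lattice, pixel-centre registered.

    ``lon0``/``lat0`` are the centre of pixel ``[0, 0]``; ``dlon`` is positive
    eastward, ``dlat`` negative for north-up rasters.
    """

    lon0: float = 80.0
    lat0: float = 45.0
    dlon: float = 0.05
    dlat: float = -0.05

    def lons(self, ncols: int) -> np.ndarray:
        return self.lon0 + self.dlon * np.arange(ncols)

    def lats(self, nrows: int) -> np.ndarray:
        return self.lat0 + self.dlat * np.arange(nrows)


@dataclass
class GridStack:
    """One variable on a (time, rows, cols) lattice with a missing-value mask."""

    values: np.ndarray
    mask: np.ndarray
    units: str
    time: pd.DatetimeIndex
    geo: GridGeo = field(default_factory=GridGeo)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError(f"values must be (time, rows, cols); got {self.values.shape}")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")
        if not self.units:
            raise ValueError("units must be non-empty")
        self.time = pd.DatetimeIndex(self.time)
        if len(self.time) != self.values.shape[0]:
            raise ValueError("time axis length must match values.shape[0]")
        if len(self.time) > 1 and not self.time.is_monotonic_increasing:
            raise ValueError("time axis must be strictly increasing")

    # -- convenience ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    def data_nan(self) -> np.ndarray:
        """Values with masked cells replaced by NaN."""
        out = self.values.copy()
        out[self.mask] = np.nan
        return out

    def copy(self) -> "GridStack":
        return GridStack(self.values.copy(), self.mask.copy(), self.units,
                         self.time.copy(), self.geo)

    def like(self, values: np.ndarray, mask: np.ndarray | None = None,
             units: str | None = None,
             time: pd.DatetimeIndex | None = None) -> "GridStack":
        """New stack sharing this one's georeference (and time axis by default)."""
        return GridStack(values,
                         mask if mask is not None else ~np.isfinite(values),
                         units if units is not None else self.units,
                         time if time is not None else self.time,
                         self.geo)

    def lat_field(self) -> np.ndarray:
        """(rows, cols) array of pixel-centre latitudes."""
        nrows, ncols = self.grid_shape
        return np.repeat(self.geo.lats(nrows)[:, None], ncols, axis=1)

    # -- I/O -----------------------------------------------------------------

    def to_dataarray(self, name: str = "value") -> xr.DataArray:
        nrows, ncols = self.grid_shape
        return xr.DataArray(
            self.data_nan(),
            dims=("time", "lat", "lon"),
            coords={"time": self.time,
                    "lat": self.geo.lats(nrows),
                    "lon": self.geo.lons(ncols)},
            name=name,
            attrs={"units": self.units},
        )

    def to_netcdf(self, path: str | Path, name: str = "value") -> None:
        da = self.to_dataarray(name)
        da.to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataarray(cls, da: xr.DataArray, units: str | None = None) -> "GridStack":
        vals = np.asarray(da.values, dtype=float)
        lat = np.asarray(da["lat"].values)
        lon = np.asarray(da["lon"].values)
        geo = GridGeo(lon0=float(lon[0]), lat0=float(lat[0]),
                      dlon=float(lon[1] - lon[0]) if lon.size > 1 else 0.05,
                      dlat=float(lat[1] - lat[0]) if lat.size > 1 else -0.05)
        return cls(vals, ~np.isfinite(vals),
                   units or str(da.attrs.get("units", "unknown")),
                   pd.DatetimeIndex(da["time"].values), geo)

    @classmethod
    def from_netcdf(cls, path: str | Path, name: str = "value") -> "GridStack":
        with xr.open_dataset(path, engine="scipy") as ds:
            da = ds[name].load()
        return cls.from_dataarray(da)


# Nine grassland classes (byte codes for the categorical raster).
GRASSLAND_CLASSES: dict[int, str] = {
    1: "alpine meadow",
    2: "alpine steppe",
    3: "temperate meadow steppe",
    4: "temperate typical steppe",
    5: "montane meadow",
    6: "warm-temperate tussock and shrub-tussock",
    7: "tropical tussock and shrub-tussock",
    8: "temperate desert steppe",
    9: "temperate meadow",
}


@dataclass
class TypeMap:
    """Categorical grassland-type raster (byte codes 1-9, 0 = no grassland)."""

    codes: np.ndarray
    geo: GridGeo = field(default_factory=GridGeo)
    legend: dict[int, str] = field(default_factory=lambda: dict(GRASSLAND_CLASSES))

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2:
            raise ValueError("TypeMap codes must be 2-D")
        if self.codes.size == 0:
            raise ValueError("TypeMap grid is empty")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.codes.shape

    def present_codes(self) -> list[int]:
        return sorted(int(c) for c in np.unique(self.codes) if c != 0)

    def to_tiff(self, path: str | Path) -> None:
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.codes)
        legend = pd.DataFrame(
            {"code": list(self.legend), "name": list(self.legend.values())})
        legend["lon0"] = self.geo.lon0
        legend["lat0"] = self.geo.lat0
        legend["dlon"] = self.geo.dlon
        legend["dlat"] = self.geo.dlat
        legend.to_csv(path.with_suffix(".legend.csv"), index=False)

    @classmethod
    def from_tiff(cls, path: str | Path) -> "TypeMap":
        import tifffile

        path = Path(path)
        codes = tifffile.imread(path)
        legend_path = path.with_suffix(".legend.csv")
        legend = dict(GRASSLAND_CLASSES)
        geo = GridGeo()
        if legend_path.exists():
            tab = pd.read_csv(legend_path)
            legend = dict(zip(tab["code"].astype(int), tab["name"]))
            row = tab.iloc[0]
            geo = GridGeo(float(row["lon0"]), float(row["lat0"]),
                          float(row["dlon"]), float(row["dlat"]))
        return cls(codes, geo, legend)


def write_category_tiff(path: str | Path, codes: np.ndarray, geo: GridGeo,
                        legend: dict[int, str]) -> None:
    """Write any small categorical raster (trend class, flags) as TIFF + legend."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.asarray(codes, dtype=np.uint8))
    pd.DataFrame({"code": list(legend), "name": list(legend.values()),
                  "lon0": geo.lon0, "lat0": geo.lat0,
                  "dlon": geo.dlon, "dlat": geo.dlat}).to_csv(
        path.with_suffix(".legend.csv"), index=False)
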