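"""Cleaning and harmonisation of input stacks.

The NDVI record is cleaned per pixel in a fixed order: linear gap-fill,
interquartile-range outlier screen over the full record, re-fill of the
removed cells, Savitzky-Golay smoothing, then maximum-value compositing to a
monthly cadence.  Outliers must not anchor the interpolation, and compositing
last matches how monthly vegetation-index products are built.

Also here: thickness-weighted combination of the two soil-moisture layers,
vapour-pressure deficit from the Tetens saturation curve, grid resampling,
and an inverse-distance-weighting path for station CSVs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .grids import GridGeo, GridStack


@dataclass
class PreprocessReport:
    """Audit trail of the per-pixel cleaning steps."""

    n_filled: int = 0
    n_outliers_removed: int = 0
    sg_window: int = 5
    sg_order: int = 2
    outlier_flags: np.ndarray | None = field(default=None, repr=False)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d.pop("outlier_flags")
        Path(path).write_text(json.dumps(d, indent=2))


def fill_missing_linear(series: np.ndarray, mask: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Fill masked cells of a 1-D series by linear interpolation.

    Interior gaps are interpolated between the nearest observed neighbours;
    leading/trailing gaps take the nearest observed value.  Returns the filled
    series and an all-False mask.
    """
    series = np.asarray(series, dtype=float)
    mask = np.asarray(mask, dtype=bool) | ~np.isfinite(series)
    obs = ~mask
    if obs.sum() == 0:
        raise ValueError("unfillable series: all values missing")
    idx = np.arange(series.size)
    filled = np.interp(idx, idx[obs], series[obs])  # np.interp clamps at edges
    return filled, np.zeros_like(mask)


def remove_outliers_iqr(series: np.ndarray, mask: np.ndarray | None = None,
                        k: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Mask cells outside [Q1 − k·IQR, Q3 + k·IQR] of the observed values.

    Quartiles use the linear-interpolation rule between order statistics
    (numpy's default). Returns (mask including outliers, outlier flags).
    """
    if k <= 0:
        raise ValueError("IQR multiplier k must be > 0")
    series = np.asarray(series, dtype=float)
    mask = (np.zeros(series.shape, bool) if mask is None
            else np.asarray(mask, dtype=bool))
    obs = series[~mask]
    if obs.size < 4:
        raise ValueError("need at least 4 observed points for the IQR screen")
    q1, q3 = np.quantile(obs, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    flags = ~mask & ((series < lo) | (series > hi))
    return mask | flags, flags


def sg_filter(series: np.ndarray, window: int = 5, order: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing: local least-squares polynomial per window.

    Edges use polynomial extrapolation from the first/last full window
    (scipy's ``interp`` mode).  Requires a gap-free series.
    """
    series = np.asarray(series, dtype=float)
    if window % 2 == 0:
        raise ValueError("SG window must be odd")
    if order >= window:
        raise ValueError("SG polynomial order must be < window")
    if series.size < window:
        raise ValueError("series shorter than SG window")
    if not np.all(np.isfinite(series)):
        raise ValueError("SG filter requires a gap-free series; run gap-fill first")
    return savgol_filter(series, window_length=window, polyorder=order, mode="interp")


def clean_series(series: np.ndarray, mask: np.ndarray, k: float = 1.5,
                 window: int = 5, order: int = 2
                 ) -> tuple[np.ndarray, int, int]:
    """Gap-fill → IQR screen → re-fill → SG smooth one pixel's series.

    Returns (cleaned series, n cells filled in the first pass, n outliers).
    """
    mask = np.asarray(mask, dtype=bool) | ~np.isfinite(series)
    n_gaps = int(mask.sum())
    filled, _ = fill_missing_linear(series, mask)
    full_mask, flags = remove_outliers_iqr(filled, k=k)
    n_out = int(flags.sum())
    if n_out:
        filled, _ = fill_missing_linear(filled, full_mask)
    return sg_filter(filled, window, order), n_gaps, n_out


def clean_ndvi_stack(ndvi: GridStack, k: float = 1.5, window: int = 5,
                     order: int = 2) -> tuple[GridStack, GridStack, PreprocessReport]:
    """Apply the full per-pixel cleaning chain and the monthly composite.

    Returns (cleaned sub-monthly stack, monthly MVC stack, report).  The
    report's ``outlier_flags`` has the input stack's shape.
    """
    vals = ndvi.values
    nt, nr, nc = vals.shape
    cleaned = np.empty_like(vals, dtype=float)
    flags = np.zeros(vals.shape, dtype=bool)
    n_filled = n_out = 0
    for r in range(nr):
        for c in range(nc):
            m = ndvi.mask[:, r, c]
            filled, _ = fill_missing_linear(vals[:, r, c], m)
            full_mask, f = remove_outliers_iqr(filled, k=k)
            flags[:, r, c] = f
            if f.any():
                filled, _ = fill_missing_linear(filled, full_mask)
            cleaned[:, r, c] = sg_filter(filled, window, order)
            n_filled += int(m.sum())
            n_out += int(f.sum())
    clean_stack = ndvi.like(cleaned, np.zeros_like(flags))
    monthly = mvc_monthly(clean_stack)
    report = PreprocessReport(n_filled=n_filled, n_outliers_removed=n_out,
                              sg_window=window, sg_order=order,
                              outlier_flags=flags)
    return clean_stack, monthly, report


def mvc_monthly(stack: GridStack) -> GridStack:
    """Maximum-value composite to monthly cadence.

    Per pixel-month the output is the maximum over that month's unmasked
    observations; months with no observation are masked.
    """
    if stack.values.size == 0:
        raise ValueError("empty stack")
    vals = stack.data_nan()
    key = stack.time.year * 12 + (stack.time.month - 1)
    out_vals, out_time = [], []
    for ym in np.unique(key):
        sel = key == ym
        with np.errstate(all="ignore"):
            out_vals.append(np.nanmax(vals[sel], axis=0))
        y, m = divmod(int(ym), 12)
        out_time.append(pd.Timestamp(year=y, month=m + 1, day=15))
    arr = np.stack(out_vals)
    return GridStack(arr, ~np.isfinite(arr), stack.units,
                     pd.DatetimeIndex(out_time), stack.geo)


#: Layer thicknesses (cm) of the two reanalysis soil-moisture levels.
SM_LAYERS_CM = (7.0, 21.0)


def combine_soil_moisture(sm_top: GridStack, sm_mid: GridStack) -> GridStack:
    """Thickness-weighted 0–28 cm soil moisture: (7·top + 21·mid)/28."""
    if sm_top.shape != sm_mid.shape or not sm_top.time.equals(sm_mid.time):
        raise ValueError("soil-moisture layers are misaligned")
    w_top = SM_LAYERS_CM[0] / sum(SM_LAYERS_CM)
    w_mid = SM_LAYERS_CM[1] / sum(SM_LAYERS_CM)
    out = w_top * sm_top.data_nan() + w_mid * sm_mid.data_nan()
    return sm_top.like(out, ~np.isfinite(out))


def tetens_es(t_celsius: np.ndarray) -> np.ndarray:
    """Tetens saturation vapour pressure (kPa) at air temperature (°C)."""
    t = np.asarray(t_celsius, dtype=float)
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def compute_vpd(t: GridStack, rh: GridStack) -> GridStack:
    """Vapour pressure deficit VPD = es(T)·(1 − RH/100), kPa."""
    rh_vals = rh.data_nan()
    with np.errstate(invalid="ignore"):
        bad = (rh_vals < 0) | (rh_vals > 100)
    if bad.any():
        raise ValueError("relative humidity outside [0, 100] %")
    vpd = tetens_es(t.data_nan()) * (1.0 - rh_vals / 100.0)
    return t.like(vpd, ~np.isfinite(vpd), units="kPa")


def resample_grid(stack: GridStack, target: GridGeo,
                  target_shape: tuple[int, int],
                  method: str = "bilinear") -> GridStack:
    """Resample onto a target lattice by nearest neighbour or bilinear
    interpolation.

    Bilinear masks any target cell whose 2×2 source neighbourhood touches a
    masked cell; nearest propagates the nearest cell's mask.  Raises if the
    extents do not overlap.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown resampling method {method!r}")
    nt, nr, nc = stack.shape
    src_lon, src_lat = stack.geo.lons(nc), stack.geo.lats(nr)
    tr, tc = target_shape
    tgt_lon, tgt_lat = target.lons(tc), target.lats(tr)

    def frac_index(coords: np.ndarray, x: np.ndarray) -> np.ndarray:
        step = coords[1] - coords[0] if coords.size > 1 else 1.0
        return (x - coords[0]) / step

    fi = frac_index(src_lat, tgt_lat)   # fractional row index
    fj = frac_index(src_lon, tgt_lon)
    if fi.max() < 0 or fi.min() > nr - 1 or fj.max() < 0 or fj.min() > nc - 1:
        raise ValueError("target grid extent is disjoint from the source")

    vals = stack.data_nan()
    out = np.empty((nt, tr, tc))
    if method == "nearest":
        ri = np.clip(np.round(fi).astype(int), 0, nr - 1)
        cj = np.clip(np.round(fj).astype(int), 0, nc - 1)
        out[:] = vals[:, ri[:, None], cj[None, :]]
    else:
        i0 = np.clip(np.floor(fi).astype(int), 0, nr - 2 if nr > 1 else 0)
        j0 = np.clip(np.floor(fj).astype(int), 0, nc - 2 if nc > 1 else 0)
        di = np.clip(fi - i0, 0.0, 1.0)[:, None]
        dj = np.clip(fj - j0, 0.0, 1.0)[None, :]
        i1 = np.minimum(i0 + 1, nr - 1)
        j1 = np.minimum(j0 + 1, nc - 1)
        v00 = vals[:, i0[:, None], j0[None, :]]
        v01 = vals[:, i0[:, None], j1[None, :]]
        v10 = vals[:, i1[:, None], j0[None, :]]
        v11 = vals[:, i1[:, None], j1[None, :]]
        out = (v00 * (1 - di) * (1 - dj) + v01 * (1 - di) * dj
               + v10 * di * (1 - dj) + v11 * di * dj)
    return GridStack(out, ~np.isfinite(out), stack.units, stack.time, target)


def idw_station_grid(stations: pd.DataFrame, variable: str, geo: GridGeo,
                     grid_shape: tuple[int, int], power: float = 2.0,
                     k_neighbours: int = 8) -> GridStack:
    """Grid a station table by inverse-distance weighting (power 2, k=8).

    ``stations`` columns: station_id, lat, lon, date, and the variable.
    One output layer per unique date.
    """
    from scipy.spatial import cKDTree

    nr, nc = grid_shape
    lons, lats = np.meshgrid(geo.lons(nc), geo.lats(nr))
    pts = np.column_stack([lons.ravel(), lats.ravel()])
    dates = np.sort(stations["date"].unique())
    out = np.empty((dates.size, nr, nc))
    for i, d in enumerate(dates):
        sub = stations[stations["date"] == d]
        xy = sub[["lon", "lat"]].to_numpy(dtype=float)
        v = sub[variable].to_numpy(dtype=float)
        kk = min(k_neighbours, len(sub))
        dist, idx = cKDTree(xy).query(pts, k=kk)
        dist = np.atleast_2d(dist.T).T
        idx = np.atleast_2d(idx.T).T
        w = 1.0 / np.maximum(dist, 1e-12) ** power
        exact = dist[:, 0] < 1e-12
        est = (w * v[idx]).sum(axis=1) / w.sum(axis=1)
        est[exact] = v[idx[exact, 0]]
        out[i] = est.reshape(nr, nc)
    return GridStack(out, np.zeros(out.shape, bool), variable,
                     pd.DatetimeIndex(dates), geo)
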