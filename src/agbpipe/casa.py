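"""CASA light-use-efficiency model for monthly grassland NPP.

Monthly net primary production per pixel is the product of absorbed
photosynthetically active radiation and a light-use efficiency damped by
temperature and water stress:

    NPP = APAR · ε,   APAR = SOL · FPAR · 0.5,   ε = Tε1 · Tε2 · Wε · ε_max

with the standard grassland sub-models:

* FPAR — linear ramp in NDVI between per-type (ndvi_min, ndvi_max), mapped to
  [fpar_min, fpar_max] and clipped (fpar_max capped at 0.95).
* Tε1  — quadratic in the optimum temperature T_opt, zeroed below −10 °C.
* Tε2  — double-logistic penalty for departure of monthly temperature from
  T_opt.
* Wε   — moisture limitation in [0.5, 1], either from the ratio of estimated
  actual to potential evapotranspiration (E/Ep with E = min(PPT, PET)) or from
  a supplied soil-moisture ratio.

ε_max defaults to 0.542 g C/MJ for grassland; all constants are per-type
parameters in :class:`CasaParams` and ship with a packaged default table.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .grids import GridStack, TypeMap

#: Photosynthetically active fraction of incoming shortwave radiation.
PAR_FRACTION = 0.5


@dataclass(frozen=True)
class TypeCasa:
    eps_max: float      # g C/MJ
    ndvi_min: float
    ndvi_max: float
    fpar_min: float
    fpar_max: float

    def __post_init__(self) -> None:
        if self.ndvi_min >= self.ndvi_max:
            raise ValueError("ndvi_min must be < ndvi_max")
        if not (0 <= self.fpar_min < self.fpar_max <= 0.95):
            raise ValueError("need 0 <= fpar_min < fpar_max <= 0.95")
        if self.eps_max <= 0:
            raise ValueError("eps_max must be > 0")


@dataclass
class CasaParams:
    """Per-type CASA constants keyed by grassland class code."""

    table: dict[int, TypeCasa] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "CasaParams":
        with resources.files("agbpipe.data").joinpath("casa_params.csv").open() as fh:
            return cls.from_csv(fh)

    @classmethod
    def from_csv(cls, path_or_buf) -> "CasaParams":
        df = pd.read_csv(path_or_buf)
        return cls({int(r.code): TypeCasa(float(r.eps_max), float(r.ndvi_min),
                                          float(r.ndvi_max), float(r.fpar_min),
                                          float(r.fpar_max))
                    for r in df.itertuples()})

    def __getitem__(self, code: int) -> TypeCasa:
        try:
            return self.table[int(code)]
        except KeyError:
            raise KeyError(f"no CASA parameters for class code {code}") from None


@dataclass
class NppField:
    npp: GridStack      # g C/m²/month
    apar: GridStack     # MJ/m²/month
    fpar: GridStack
    t_eps1: GridStack
    t_eps2: GridStack
    w_eps: GridStack


def compute_fpar(ndvi: GridStack, params: CasaParams, type_map: TypeMap) -> GridStack:
    """FPAR from NDVI by the per-type linear ramp, clipped to its bounds."""
    if type_map.grid_shape != ndvi.grid_shape:
        raise ValueError("type map and NDVI grids are misaligned")
    vals = ndvi.data_nan()
    fpar = np.full_like(vals, np.nan)
    for code in type_map.present_codes():
        p = params[code]
        sel = type_map.codes == code
        ramp = p.fpar_min + (vals[:, sel] - p.ndvi_min) / (p.ndvi_max - p.ndvi_min) \
            * (p.fpar_max - p.fpar_min)
        fpar[:, sel] = np.clip(ramp, p.fpar_min, p.fpar_max)
    return ndvi.like(fpar, ~np.isfinite(fpar), units="1")


def compute_apar(sol: GridStack, fpar: GridStack) -> GridStack:
    """APAR = SOL × FPAR × 0.5 (MJ/m²/month)."""
    sol_vals = sol.data_nan()
    if np.nanmin(sol_vals) < 0:
        raise ValueError("solar radiation must be non-negative")
    apar = sol_vals * fpar.data_nan() * PAR_FRACTION
    return sol.like(apar, ~np.isfinite(apar), units="MJ/m2")


def temperature_stress(t_monthly: GridStack, t_opt: np.ndarray
                       ) -> tuple[GridStack, GridStack]:
    """Temperature-stress factors Tε1 (optimum-climate term) and Tε2.

    ``t_opt`` is a (rows, cols) map of the optimum temperature, conventionally
    the mean temperature of the month of peak NDVI.
    """
    t = t_monthly.data_nan()
    t_opt = np.asarray(t_opt, dtype=float)
    te1 = 0.8 + 0.02 * t_opt - 0.0005 * t_opt ** 2
    te1 = np.maximum(te1, 0.0)
    te1 = np.broadcast_to(te1, t.shape).copy()
    te1[t <= -10.0] = 0.0
    te1[~np.isfinite(t)] = np.nan

    te2 = 1.1814 / ((1.0 + np.exp(0.2 * (t_opt - 10.0 - t)))
                    * (1.0 + np.exp(0.3 * (-t_opt - 10.0 + t))))
    return (t_monthly.like(te1, ~np.isfinite(te1), units="1"),
            t_monthly.like(te2, ~np.isfinite(te2), units="1"))


def water_stress(ppt: GridStack | None = None, pet: GridStack | None = None,
                 sm_ratio: GridStack | None = None) -> GridStack:
    """Moisture limitation Wε ∈ [0.5, 1].

    Default mode uses precipitation and potential evapotranspiration:
    Wε = 0.5 + 0.5·E/Ep with E = min(PPT, PET).  If ``sm_ratio`` (soil
    moisture over field capacity) is supplied it is used instead:
    Wε = 0.5 + 0.5·clip(SM/SM_fc, 0, 1).
    """
    if sm_ratio is not None:
        ratio = np.clip(sm_ratio.data_nan(), 0.0, 1.0)
        ref = sm_ratio
    elif ppt is not None and pet is not None:
        pet_vals = pet.data_nan()
        if np.nanmin(pet_vals) <= 0:
            raise ValueError("PET must be positive where evaluated")
        ratio = np.minimum(ppt.data_nan(), pet_vals) / pet_vals
        ref = ppt
    else:
        raise ValueError("supply either (ppt, pet) or sm_ratio")
    w = 0.5 + 0.5 * ratio
    return ref.like(w, ~np.isfinite(w), units="1")


def compute_npp(apar: GridStack, t_eps1: GridStack, t_eps2: GridStack,
                w_eps: GridStack, eps_max: np.ndarray | float,
                fpar: GridStack | None = None) -> NppField:
    """NPP = APAR · Tε1 · Tε2 · Wε · ε_max, floored at zero.

    ``eps_max`` may be a scalar or a (rows, cols) per-pixel map (built from a
    type map with :func:`eps_max_field`).
    """
    lue = t_eps1.data_nan() * t_eps2.data_nan() * w_eps.data_nan() * np.asarray(eps_max)
    npp = np.maximum(apar.data_nan() * lue, 0.0)
    return NppField(
        npp=apar.like(npp, ~np.isfinite(npp), units="gC/m2"),
        apar=apar,
        fpar=fpar if fpar is not None else apar.like(np.full(apar.shape, np.nan), units="1"),
        t_eps1=t_eps1, t_eps2=t_eps2, w_eps=w_eps,
    )


def eps_max_field(type_map: TypeMap, params: CasaParams) -> np.ndarray:
    """(rows, cols) map of ε_max; NaN outside grassland."""
    out = np.full(type_map.grid_shape, np.nan)
    for code in type_map.present_codes():
        out[type_map.codes == code] = params[code].eps_max
    return out


def compute_topt(ndvi_monthly: GridStack, t_monthly: GridStack) -> np.ndarray:
    """Optimum temperature per pixel: climatological mean temperature of the
    calendar month whose climatological NDVI peaks."""
    months = ndvi_monthly.time.month
    ndvi_clim = np.full((12,) + ndvi_monthly.grid_shape, np.nan)
    t_clim = np.full((12,) + t_monthly.grid_shape, np.nan)
    nd, tv = ndvi_monthly.data_nan(), t_monthly.data_nan()
    for m in range(1, 13):
        sel = months == m
        if sel.any():
            ndvi_clim[m - 1] = np.nanmean(nd[sel], axis=0)
            t_clim[m - 1] = np.nanmean(tv[sel], axis=0)
    peak = np.nanargmax(np.nan_to_num(ndvi_clim, nan=-np.inf), axis=0)
    return np.take_along_axis(t_clim, peak[None], axis=0)[0]


def hamon_pet(t_monthly: GridStack) -> GridStack:
    """Hamon potential evapotranspiration (mm/month) from temperature and
    day length at each pixel's latitude.

    PET_day = 29.8 · D · es(T)/(T + 273.2), with D the day length in hours and
    es the Tetens saturation vapour pressure (kPa); summed over the month.
    Floored at a small positive value so the moisture ratio stays defined in
    frozen months.
    """
    t = t_monthly.data_nan()
    lat = np.deg2rad(t_monthly.lat_field())
    es = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    pet = np.empty_like(t)
    for i, stamp in enumerate(t_monthly.time):
        ndays = calendar.monthrange(stamp.year, stamp.month)[1]
        doy = stamp.replace(day=15).dayofyear
        decl = 0.409 * np.sin(2 * np.pi * doy / 365.0 - 1.39)
        cos_h = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
        day_len = 24.0 / np.pi * np.arccos(cos_h)
        pet[i] = 29.8 * day_len * es[i] / (t[i] + 273.2) * ndays
    pet = np.maximum(pet, 1e-6)
    return t_monthly.like(pet, ~np.isfinite(pet), units="mm")


SEASON_MONTHS = {"spring": (3, 4, 5), "summer": (6, 7, 8),
                 "autumn": (9, 10, 11), "winter": (12, 1, 2)}


def aggregate(stack: GridStack, period: str, reducer: str = "sum",
              on_incomplete: str = "raise") -> GridStack:
    """Aggregate a monthly stack to annual or seasonal values per pixel.

    ``period`` is ``annual`` or a season name (spring = MAM, summer = JJA,
    autumn = SON, winter = DJF with December taken from the preceding year, so
    winter of year y spans Dec y−1 … Feb y).  ``reducer`` is ``sum`` (fluxes
    like NPP) or ``mean`` (state variables).  Years with missing months for
    the requested period raise, listing the missing months; pass
    ``on_incomplete="skip"`` to drop them instead (the cross-year winter
    convention always truncates the record's first and last winter).
    """
    if on_incomplete not in ("raise", "skip"):
        raise ValueError("on_incomplete must be 'raise' or 'skip'")
    if reducer not in ("sum", "mean"):
        raise ValueError(f"unknown reducer {reducer!r}")
    years = stack.time.year
    months = stack.time.month
    if period == "annual":
        labels = years
        needed = set(range(1, 13))
    elif period in SEASON_MONTHS:
        want = SEASON_MONTHS[period]
        # winter: December belongs to the following year's winter
        labels = np.where(months == 12, years + 1, years) if period == "winter" else years
        needed = set(want)
    else:
        raise ValueError(f"unknown period {period!r}")

    vals = stack.data_nan()
    out_years, out = [], []
    for y in np.unique(labels):
        sel = labels == y
        if period != "annual":
            sel = sel & np.isin(months, list(SEASON_MONTHS.get(period, range(1, 13))))
        got = set(months[sel])
        if got != needed:
            if on_incomplete == "skip":
                continue
            missing = sorted(needed - got)
            raise ValueError(f"period {period!r} of year {y} missing months {missing}")
        block = vals[sel]
        out.append(np.sum(block, axis=0) if reducer == "sum" else np.mean(block, axis=0))
        out_years.append(int(y))
    if not out:
        raise ValueError(f"no complete {period!r} period in the record")
    arr = np.stack(out)
    time = pd.DatetimeIndex([pd.Timestamp(year=y, month=12, day=31) for y in out_years])
    return GridStack(arr, ~np.isfinite(arr), stack.units, time, stack.geo)
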