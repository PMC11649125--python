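"""Synthetic gridded scenarios with known ground truth.

Generates everything the pipeline consumes — a sub-monthly NDVI record with
seasonal cycle, noise, gaps and spike outliers; monthly meteorology with
configurable linear trends; two-layer soil moisture; a contiguous
grassland-type map; an annual grazing-intensity field — together with the
truth needed to score every downstream stage: the noise-free NDVI, the NPP
surface implied by the forward model on clean inputs, an annual truth AGB
with an injected linear trend and planted driver effects, and the exact
positions of injected gaps and outliers.

Truth AGB is log-linear in the standardised drivers plus Gaussian noise:

    AGB(p, y) = base·f(p)·exp(Σ_d e_d·z_d(p, y)) + s·(y − ȳ) + ε,  ε ~ N(0, σ)

so trend recovery (s), driver-sign recovery (e_d) and random-forest
importance ordering are all analytically checkable.  Upward ×2 NDVI spikes
are placed in growing-season cells, where doubling carries the value past the
interquartile fences of the full record — the screen has unambiguous targets
(a doubled winter NDVI is indistinguishable from the seasonal minimum).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy import ndimage

from . import casa as casa_mod
from . import preprocess as prep
from .grids import GRASSLAND_CLASSES, GridGeo, GridStack, TypeMap

MET_VARS = ("T", "PPT", "SR", "RH", "SM")

_DEFAULT_NOISE = {"NDVI": 0.02, "T": 0.5, "PPT": 8.0, "SR": 15.0,
                  "RH": 3.0, "SM": 0.01, "GI": 0.15, "AGB": 10.0}


@dataclass
class SyntheticScenario:
    """Full generator configuration; same seed ⇒ bit-identical output."""

    n_years: int = 10
    steps_per_month: int = 2
    grid_shape: tuple[int, int] = (12, 12)
    type_fractions: dict[int, float] = field(
        default_factory=lambda: {1: 0.4, 4: 0.4, 8: 0.2})
    ndvi_baseline: float = 0.10
    ndvi_amplitude: float = 0.50
    gap_rate: float = 0.05
    outlier_rate: float = 0.02
    met_trends: dict[str, float] = field(default_factory=dict)  # units/yr
    driver_effects: dict[str, float] = field(default_factory=dict)  # per SD, log scale
    agb_trend: float = 0.0       # g/m²/yr injected into truth AGB
    agb_base: float = 150.0      # g/m²
    noise_sd: dict[str, float] = field(default_factory=dict)
    start_year: int = 1981
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if self.steps_per_month not in (1, 2):
            raise ValueError("steps_per_month must be 1 or 2")
        rows, cols = self.grid_shape
        if rows < 1 or cols < 1:
            raise ValueError("grid_shape must be positive")
        total = sum(self.type_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type_fractions must sum to 1; got {total}")
        for code in self.type_fractions:
            if int(code) not in GRASSLAND_CLASSES:
                raise ValueError(f"type_fractions: unknown class code {code}")
        for name, rate in (("gap_rate", self.gap_rate),
                           ("outlier_rate", self.outlier_rate)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]; got {rate}")
        for d in self.driver_effects:
            if d not in ("T", "PPT", "VPD", "SR", "RH", "SM", "GI"):
                raise ValueError(f"driver_effects: unknown driver {d!r}")

    def noise(self, var: str) -> float:
        return float(self.noise_sd.get(var, _DEFAULT_NOISE[var]))


@dataclass
class SyntheticInputs:
    """What the pipeline sees: degraded NDVI plus meteorology and ancillary."""

    ndvi: GridStack          # sub-monthly, with gaps masked and spikes injected
    t: GridStack             # °C, monthly
    ppt: GridStack           # mm/month
    sr: GridStack            # MJ/m²/month
    rh: GridStack            # %, monthly
    sm_top: GridStack        # m³/m³, 0-7 cm
    sm_mid: GridStack        # m³/m³, 7-28 cm
    gi_annual: GridStack     # LSU/ha, annual
    type_map: TypeMap


@dataclass
class SyntheticTruth:
    """Ground truth and bookkeeping for scoring the pipeline."""

    ndvi_smooth: GridStack               # noise-free NDVI on the ndvi axis
    npp_true: GridStack                  # g C/m²/month, forward model on clean inputs
    agb_true: GridStack                  # g/m², annual
    injected_slopes: np.ndarray          # (rows, cols) g/m²/yr
    gap_positions: np.ndarray            # bool, ndvi axis
    outlier_positions: np.ndarray        # bool, ndvi axis
    drivers_annual: dict[str, GridStack]  # seven standardisable driver stacks
    driver_effects: dict[str, float]
    noise_sd: dict[str, float]
    npp_rmse_bound: float                # admissible RMSE of recovered vs true NPP


def inject_trend(series: np.ndarray, slope: float,
                 time_step: float = 1.0) -> np.ndarray:
    """Add an exact linear ramp of ``slope`` (units per year) to a series.

    ``time_step`` is the spacing of consecutive samples in years; the
    operation is inverted by injecting ``-slope``.
    """
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    series = np.asarray(series, dtype=float)
    ramp = slope * time_step * np.arange(series.shape[0], dtype=float)
    return series + ramp.reshape((-1,) + (1,) * (series.ndim - 1))


def make_type_map(grid_shape: tuple[int, int], type_fractions: dict[int, float],
                  seed: int, geo: GridGeo | None = None) -> TypeMap:
    """Contiguous type map with per-class pixel counts matched to the
    requested fractions by largest-remainder rounding (within 1 pixel).

    Patches are grown from seeded nuclei by randomised breadth-first
    accretion, so per-type summaries are spatially coherent rather than
    salt-and-pepper.
    """
    rows, cols = grid_shape
    n = rows * cols
    if n == 0:
        raise ValueError("empty grid")
    codes_order = sorted(type_fractions)
    fracs = np.array([type_fractions[c] for c in codes_order], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("type fractions must sum to 1")

    # largest-remainder apportionment of n pixels
    quota = fracs * n
    counts = np.floor(quota).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:short]] += 1

    rng = np.random.default_rng(seed)
    assigned = np.zeros((rows, cols), dtype=np.uint8)
    need = dict(zip(codes_order, counts.tolist()))
    frontiers: dict[int, list[tuple[int, int]]] = {}

    def seed_nucleus(code: int) -> None:
        free = np.argwhere(assigned == 0)
        pick = free[rng.integers(len(free))]
        assigned[pick[0], pick[1]] = code
        need[code] -= 1
        frontiers[code] = [(int(pick[0]), int(pick[1]))]

    for code in codes_order:
        if need[code] > 0:
            seed_nucleus(code)

    active = [c for c in codes_order if need[c] > 0]
    while active:
        for code in list(active):
            if need[code] == 0:
                active.remove(code)
                continue
            grown = False
            while frontiers[code]:
                k = rng.integers(len(frontiers[code]))
                r, c = frontiers[code][k]
                nbrs = [(r + dr, c + dc) for dr, dc in
                        ((1, 0), (-1, 0), (0, 1), (0, -1))
                        if 0 <= r + dr < rows and 0 <= c + dc < cols
                        and assigned[r + dr, c + dc] == 0]
                if not nbrs:
                    frontiers[code].pop(k)
                    continue
                nr, nc = nbrs[rng.integers(len(nbrs))]
                assigned[nr, nc] = code
                need[code] -= 1
                frontiers[code].append((nr, nc))
                grown = True
                break
            if not grown and need[code] > 0:
                if (assigned == 0).any():
                    seed_nucleus(code)
                else:
                    need[code] = 0
            if need[code] == 0 and code in active:
                active.remove(code)
    return TypeMap(assigned, geo or GridGeo())


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float = 1.0) -> np.ndarray:
    """Smooth spatial field, mean 0 and SD 1.

    The correlation length (one pixel) keeps patches spatially coherent while
    leaving enough independent patches per grid that per-pixel analyses are
    not dominated by chance field-to-field correlations.
    """
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma,
                                mode="wrap")
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def _season(month: np.ndarray) -> np.ndarray:
    """Growing-season shape: sin²(π(m−1)/12), 0 in January, peak in July."""
    return np.sin(np.pi * (np.asarray(month) - 1) / 12.0) ** 2


def generate_scenario(cfg: SyntheticScenario
                      ) -> tuple[SyntheticInputs, SyntheticTruth]:
    """Generate one scenario; deterministic given ``cfg`` (including seed)."""
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.grid_shape
    geo = GridGeo()
    ny = cfg.n_years

    # time axes
    months = pd.DatetimeIndex([pd.Timestamp(year=cfg.start_year + y, month=m, day=15)
                               for y in range(ny) for m in range(1, 13)])
    if cfg.steps_per_month == 2:
        sub = pd.DatetimeIndex(
            [pd.Timestamp(year=s.year, month=s.month, day=d)
             for s in months for d in (8, 22)])
    else:
        sub = months
    year_frac_m = (np.arange(ny * 12) / 12.0)
    month_of = months.month.to_numpy()

    type_map = make_type_map(cfg.grid_shape, cfg.type_fractions,
                             int(rng.integers(2 ** 31)), geo)

    # independent smooth spatial fields per variable (decorrelates drivers)
    fields = {v: _smooth_field(rng, cfg.grid_shape) for v in
              ("fert", "T", "PPT", "SR", "RH", "SM", "GI")}

    season_m = _season(month_of)[:, None, None]
    trend = {v: cfg.met_trends.get(v, 0.0) for v in MET_VARS}
    tshape = (ny * 12, rows, cols)

    t_vals = (5.0 + 2.0 * fields["T"] + 15.0 * season_m - 5.0
              + trend["T"] * year_frac_m[:, None, None]
              + rng.normal(0.0, cfg.noise("T"), tshape))
    ppt_base = (8.0 + 80.0 * season_m) * (1.0 + 0.3 * fields["PPT"])
    ppt_vals = np.maximum(
        ppt_base + trend["PPT"] * year_frac_m[:, None, None] / 12.0
        + rng.normal(0.0, cfg.noise("PPT"), tshape), 0.0)
    sr_vals = np.maximum(
        300.0 + 400.0 * season_m + 50.0 * fields["SR"]
        + trend["SR"] * year_frac_m[:, None, None]
        + rng.normal(0.0, cfg.noise("SR"), tshape), 0.0)
    rh_vals = np.clip(
        55.0 + 15.0 * (season_m - 0.5) + 8.0 * fields["RH"]
        + trend["RH"] * year_frac_m[:, None, None]
        + rng.normal(0.0, cfg.noise("RH"), tshape), 5.0, 95.0)
    sm_mean = np.clip(
        0.15 + 0.12 * season_m + 0.05 * fields["SM"]
        + trend["SM"] * year_frac_m[:, None, None]
        + rng.normal(0.0, cfg.noise("SM"), tshape), 0.01, 0.45)
    # top layer slightly drier and more variable than the mid layer
    sm_top_vals = np.clip(sm_mean - 0.02
                          + rng.normal(0.0, cfg.noise("SM") / 2, tshape),
                          0.005, 0.5)
    sm_mid_vals = np.clip((28.0 * sm_mean - 7.0 * sm_top_vals) / 21.0, 0.005, 0.5)

    def monthly(vals: np.ndarray, units: str) -> GridStack:
        return GridStack(vals, np.zeros(vals.shape, bool), units, months, geo)

    t_st, ppt_st = monthly(t_vals, "degC"), monthly(ppt_vals, "mm")
    sr_st, rh_st = monthly(sr_vals, "MJ/m2"), monthly(rh_vals, "%")
    sm_top_st = monthly(sm_top_vals, "m3/m3")
    sm_mid_st = monthly(sm_mid_vals, "m3/m3")

    # --- NDVI: smooth truth on the sub-monthly axis, then degrade -----------
    fert = 1.0 + 0.15 * fields["fert"]
    sub_month_frac = sub.month.to_numpy() + (sub.day.to_numpy() - 1) / 30.0
    season_sub = np.sin(np.pi * (sub_month_frac - 1) / 12.0) ** 2
    ndvi_smooth = np.clip(
        cfg.ndvi_baseline + cfg.ndvi_amplitude * season_sub[:, None, None]
        * fert[None, :, :], -0.2, 1.0)
    ndvi_obs = np.clip(ndvi_smooth
                       + rng.normal(0.0, cfg.noise("NDVI"), ndvi_smooth.shape),
                       -0.2, 1.0)

    nt_sub = len(sub)
    ncells = nt_sub * rows * cols
    n_gap = int(round(cfg.gap_rate * ncells))
    n_out = int(round(cfg.outlier_rate * ncells))

    flat_gap = rng.choice(ncells, size=n_gap, replace=False) if n_gap else \
        np.empty(0, dtype=int)
    gap_mask = np.zeros(ncells, dtype=bool)
    gap_mask[flat_gap] = True
    gap_mask = gap_mask.reshape(ndvi_smooth.shape)
    # every pixel keeps at least 4 observations (IQR screen precondition)
    for r, c in np.argwhere(gap_mask.sum(axis=0) > nt_sub - 4):
        keep = rng.choice(nt_sub, size=4, replace=False)
        gap_mask[keep, r, c] = False

    # ×2 spikes only where doubling clears the pixel's own full-record IQR
    # fence with margin — the screen gets unambiguous targets.  (A doubled
    # winter NDVI sits inside the seasonal spread, and on lush pixels the
    # clip at 1.0 can keep any spike below the fence.)
    q1, q3 = np.quantile(ndvi_obs, [0.25, 0.75], axis=0)
    fence_hi = q3 + 1.5 * (q3 - q1)
    spiked = np.clip(2.0 * ndvi_obs, -0.2, 1.0)
    eligible = np.flatnonzero(
        (~gap_mask).ravel()
        & (spiked > fence_hi[None] + 3.0 * cfg.noise("NDVI")).ravel())
    n_out = min(n_out, eligible.size)
    flat_out = rng.choice(eligible, size=n_out, replace=False) if n_out else \
        np.empty(0, dtype=int)
    out_mask = np.zeros(ncells, dtype=bool)
    out_mask[flat_out] = True
    out_mask = out_mask.reshape(ndvi_smooth.shape)

    ndvi_vals = ndvi_obs.copy()
    ndvi_vals[out_mask] = np.clip(2.0 * ndvi_vals[out_mask], -0.2, 1.0)
    ndvi_st = GridStack(ndvi_vals, gap_mask.copy(), "1", sub, geo)
    ndvi_smooth_st = GridStack(ndvi_smooth, np.zeros_like(gap_mask), "1", sub, geo)

    # --- truth NPP: forward model on the clean record -----------------------
    casa_params = casa_mod.CasaParams.default()
    ndvi_monthly_true = prep.mvc_monthly(ndvi_smooth_st)
    fpar = casa_mod.compute_fpar(ndvi_monthly_true, casa_params, type_map)
    apar = casa_mod.compute_apar(sr_st, fpar)
    topt = casa_mod.compute_topt(ndvi_monthly_true, t_st)
    te1, te2 = casa_mod.temperature_stress(t_st, topt)
    pet = casa_mod.hamon_pet(t_st)
    weps = casa_mod.water_stress(ppt=ppt_st, pet=pet)
    eps = casa_mod.eps_max_field(type_map, casa_params)
    npp_true = casa_mod.compute_npp(apar, te1, te2, weps, eps, fpar=fpar).npp

    # admissible RMSE for NPP recovery: 3·(effective NDVI noise)·|dNPP/dNDVI|
    ramp = casa_params[type_map.present_codes()[0]]
    dfpar_dndvi = (ramp.fpar_max - ramp.fpar_min) / (ramp.ndvi_max - ramp.ndvi_min)
    mean_lue = float(np.nanmean(te1.data_nan() * te2.data_nan()
                                * weps.data_nan()) * np.nanmean(eps))
    npp_rmse_bound = 3.0 * cfg.noise("NDVI") * float(np.nanmean(sr_vals)) \
        * 0.5 * dfpar_dndvi * mean_lue

    # --- annual drivers and truth AGB ---------------------------------------
    years = pd.DatetimeIndex([pd.Timestamp(year=cfg.start_year + y, month=12, day=31)
                              for y in range(ny)])

    def annual(stack: GridStack, reducer: str) -> GridStack:
        return casa_mod.aggregate(stack, "annual", reducer)

    vpd_st = prep.compute_vpd(t_st, rh_st)
    sm_comb = prep.combine_soil_moisture(sm_top_st, sm_mid_st)
    # stocking rates are skewed and strictly positive: lognormal around
    # 1 LSU/ha with a smooth spatial pattern and interannual noise
    gi_vals = np.exp(0.5 * fields["GI"]
                     + rng.normal(0.0, cfg.noise("GI"), (ny, rows, cols)))
    gi_st = GridStack(gi_vals, np.zeros(gi_vals.shape, bool), "LSU/ha", years, geo)

    drivers = {"T": annual(t_st, "mean"), "PPT": annual(ppt_st, "sum"),
               "VPD": annual(vpd_st, "mean"), "SR": annual(sr_st, "mean"),
               "RH": annual(rh_st, "mean"), "SM": annual(sm_comb, "mean"),
               "GI": gi_st}

    log_term = np.zeros((ny, rows, cols))
    effects = {d: float(cfg.driver_effects.get(d, 0.0)) for d in drivers}
    for name, stack in drivers.items():
        e = effects[name]
        if e != 0.0:
            v = stack.data_nan()
            sd = v.std()
            z = (v - v.mean()) / (sd if sd > 0 else 1.0)
            log_term += e * z
    agb_noise = rng.normal(0.0, cfg.noise("AGB"), (ny, rows, cols))
    agb_true = np.maximum(
        cfg.agb_base * fert[None] * np.exp(log_term)
        + inject_trend(np.zeros((ny, rows, cols)), cfg.agb_trend)
        - cfg.agb_trend * (ny - 1) / 2.0  # centre the ramp on the record
        + agb_noise, 0.0)
    agb_true_st = GridStack(agb_true, np.zeros(agb_true.shape, bool),
                            "g/m2", years, geo)

    inputs = SyntheticInputs(ndvi=ndvi_st, t=t_st, ppt=ppt_st, sr=sr_st,
                             rh=rh_st, sm_top=sm_top_st, sm_mid=sm_mid_st,
                             gi_annual=gi_st, type_map=type_map)
    truth = SyntheticTruth(
        ndvi_smooth=ndvi_smooth_st, npp_true=npp_true, agb_true=agb_true_st,
        injected_slopes=np.full((rows, cols), cfg.agb_trend),
        gap_positions=gap_mask, outlier_positions=out_mask,
        drivers_annual=drivers, driver_effects=effects,
        noise_sd={k: cfg.noise(k) for k in _DEFAULT_NOISE},
        npp_rmse_bound=npp_rmse_bound)
    return inputs, truth


def write_scenario(inputs: SyntheticInputs, truth: SyntheticTruth,
                   out_dir: str | Path) -> None:
    """Persist a scenario: one NetCDF per variable, TIFF type map, JSON truth
    sidecar (truth rasters as NetCDF)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("ndvi", "t", "ppt", "sr", "rh", "sm_top", "sm_mid", "gi_annual"):
        getattr(inputs, name).to_netcdf(out / f"{name}.nc", name="value")
    inputs.type_map.to_tiff(out / "type_map.tif")
    truth.npp_true.to_netcdf(out / "truth_npp.nc")
    truth.agb_true.to_netcdf(out / "truth_agb.nc")
    meta = {"driver_effects": truth.driver_effects,
            "noise_sd": truth.noise_sd,
            "npp_rmse_bound": truth.npp_rmse_bound,
            "injected_slope": float(truth.injected_slopes.flat[0])}
    (out / "truth.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
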