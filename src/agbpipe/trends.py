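"""Per-pixel trend and stability statistics.

Trend slope by the Theil-Sen estimator (median of all pairwise slopes),
monotone-trend significance by the Mann-Kendall test (normal approximation
with tie-corrected variance and continuity correction), a five-class
improvement/degradation categorisation, and interannual stability by the
coefficient of variation in five levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grids import GridStack

TREND_CATEGORIES = (
    "significant degradation",
    "slight degradation",
    "stable",
    "slight improvement",
    "significant improvement",
)

CV_LEVELS = ("low", "relatively low", "medium", "relatively high", "high")


@dataclass(frozen=True)
class TrendResult:
    slope: float
    mk_s: int
    mk_z: float
    p_value: float
    category: str


@dataclass(frozen=True)
class StabilityResult:
    cv: float
    level: str


def theil_sen(values: np.ndarray, times: np.ndarray | None = None) -> float:
    """Theil-Sen slope: median over all pairs i<j of (x_j − x_i)/(t_j − t_i)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Theil-Sen needs at least 3 points")
    t = np.arange(x.size, dtype=float) if times is None else np.asarray(times, float)
    i, j = np.triu_indices(x.size, k=1)
    return float(np.median((x[j] - x[i]) / (t[j] - t[i])))


def mann_kendall(values: np.ndarray) -> tuple[int, float, float]:
    """Mann-Kendall test: returns (S, Z, two-sided p).

    S = Σ_{i<j} sign(x_j − x_i); Var(S) carries the tie correction
    Σ t(t−1)(2t+5)/18; Z applies the ±1 continuity correction (0 when S=0);
    p is two-sided from the standard normal.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("Mann-Kendall needs at least 4 points")
    i, j = np.triu_indices(n, k=1)
    s = int(np.sign(x[j] - x[i]).sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var_s <= 0:
        return s, 0.0, 1.0
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return s, float(z), float(min(p, 1.0))


def classify_trend(slope: float, p: float, slope_threshold: float = 0.5,
                   alpha: float = 0.05) -> str:
    """Five-class trend label from (slope, p).

    |slope| < threshold → stable; otherwise the sign gives the direction and
    p < alpha upgrades 'slight' to 'significant'.
    """
    if slope_threshold < 0:
        raise ValueError("slope threshold must be non-negative")
    if abs(slope) < slope_threshold:
        return "stable"
    if slope > 0:
        return "significant improvement" if p < alpha else "slight improvement"
    return "significant degradation" if p < alpha else "slight degradation"


def trend_result(values: np.ndarray, slope_threshold: float = 0.5,
                 alpha: float = 0.05) -> TrendResult:
    slope = theil_sen(values)
    s, z, p = mann_kendall(values)
    return TrendResult(slope, s, z, p, classify_trend(slope, p, slope_threshold, alpha))


def coefficient_of_variation(values: np.ndarray) -> float:
    """Sample CV: standard deviation (n−1 denominator) over the mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least 2 points")
    mean = x.mean()
    if mean == 0:
        raise ValueError("undefined CV: zero mean")
    return float(x.std(ddof=1) / mean)


def classify_cv(cv_field: np.ndarray, breaks="quantile"
                ) -> tuple[np.ndarray, np.ndarray]:
    """Assign each pixel's CV to one of five fluctuation levels.

    ``breaks`` is either four ascending thresholds or ``"quantile"`` (the
    20/40/60/80th percentiles of valid pixels).  Returns (level-index array
    with −1 for invalid pixels, the four break values).
    """
    cv = np.asarray(cv_field, dtype=float)
    valid = np.isfinite(cv)
    if isinstance(breaks, str):
        if breaks != "quantile":
            raise ValueError(f"unknown break mode {breaks!r}")
        if valid.sum() < 5:
            raise ValueError("quantile breaks need at least 5 valid pixels")
        bks = np.quantile(cv[valid], [0.2, 0.4, 0.6, 0.8])
    else:
        bks = np.asarray(breaks, dtype=float)
        if bks.size != 4 or np.any(np.diff(bks) <= 0):
            raise ValueError("breaks must be 4 strictly ascending thresholds")
    idx = np.searchsorted(bks, cv[valid], side="right")
    out = np.full(cv.shape, -1, dtype=int)
    out[valid] = idx
    return out, bks


def trend_stack(annual: GridStack, slope_threshold: float = 0.5,
                alpha: float = 0.05) -> dict[str, np.ndarray]:
    """Per-pixel Theil-Sen/Mann-Kendall over an annual stack.

    Returns arrays ``slope``, ``z``, ``p``, ``category`` (index into
    TREND_CATEGORIES, −1 where the series is invalid).
    """
    vals = annual.data_nan()
    nr, nc = annual.grid_shape
    slope = np.full((nr, nc), np.nan)
    z = np.full((nr, nc), np.nan)
    p = np.full((nr, nc), np.nan)
    cat = np.full((nr, nc), -1, dtype=int)
    for r in range(nr):
        for c in range(nc):
            series = vals[:, r, c]
            if not np.all(np.isfinite(series)) or series.size < 4:
                continue
            res = trend_result(series, slope_threshold, alpha)
            slope[r, c], z[r, c], p[r, c] = res.slope, res.mk_z, res.p_value
            cat[r, c] = TREND_CATEGORIES.index(res.category)
    return {"slope": slope, "z": z, "p": p, "category": cat}


def cv_stack(annual: GridStack, breaks="quantile") -> dict[str, np.ndarray]:
    """Per-pixel CV and five-level stability classification."""
    vals = annual.data_nan()
    mean = np.nanmean(vals, axis=0)
    sd = np.nanstd(vals, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean != 0, sd / mean, np.nan)
    level, bks = classify_cv(cv, breaks)
    return {"cv": cv, "level": level, "breaks": bks}


def area_fraction(category_map: np.ndarray, categories,
                  lat_field: np.ndarray | None = None,
                  mode: str = "count") -> dict:
    """Percentage of valid pixels in each category.

    ``mode="latitude-weighted"`` weights pixels by cos(latitude) using
    ``lat_field`` (degrees).  Percentages sum to 100 over valid pixels.
    """
    cat = np.asarray(category_map)
    valid = cat >= 0 if np.issubdtype(cat.dtype, np.integer) else np.isfinite(cat)
    if valid.sum() == 0:
        raise ValueError("no valid pixels to summarise")
    if mode == "latitude-weighted":
        if lat_field is None:
            raise ValueError("latitude-weighted mode needs lat_field")
        w = np.cos(np.deg2rad(np.asarray(lat_field, dtype=float)))
    elif mode == "count":
        w = np.ones(cat.shape)
    else:
        raise ValueError(f"unknown area mode {mode!r}")
    total = w[valid].sum()
    return {name: float(100.0 * w[valid & (cat == i)].sum() / total)
            for i, name in enumerate(categories)}
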