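"""Driver-biomass relationships: correlation maps and random-forest importance.

Per-pixel Pearson correlation between annual AGB and each driver with the
four-way SN/NSN/NSP/SP significance categorisation, per-grassland-type (and
per-season) correlation tables on spatial-mean series, and random-forest
relative importance of the seven drivers (T, PPT, VPD, SR, RH, SM, GI)
expressed as percentage shares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .grids import GridStack, TypeMap

DRIVERS = ("T", "PPT", "VPD", "SR", "RH", "SM", "GI")

CORRELATION_CATEGORIES = ("SN", "NSN", "NSP", "SP")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    category: str


@dataclass
class ImportanceResult:
    shares: dict[str, float]            # percent, sums to 100
    n_trees: int
    seed: int
    n_rows_used: int = 0
    n_rows_dropped: int = 0


def pearson_with_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with a two-sided t-test p-value on n−2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need aligned series with at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate series: zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def categorize_correlation(r: float, p: float, alpha: float = 0.05) -> str:
    """SN (r<0, p<α), NSN (r<0, p≥α), NSP (r>0, p≥α), SP (r>0, p<α).

    r = 0 falls in NSP (the four strict-inequality classes leave it
    unassigned; the tie is resolved to the non-significant positive class).
    """
    if not (np.isfinite(r) and np.isfinite(p)):
        raise ValueError("non-finite correlation inputs")
    if r < 0:
        return "SN" if p < alpha else "NSN"
    return "SP" if p < alpha else "NSP"


def correlation_stack(agb_annual: GridStack, driver_annual: GridStack,
                      alpha: float = 0.05) -> dict[str, np.ndarray]:
    """Per-pixel Pearson r, p and SN/NSN/NSP/SP category index."""
    a = agb_annual.data_nan()
    d = driver_annual.data_nan()
    nr, nc = agb_annual.grid_shape
    r = np.full((nr, nc), np.nan)
    p = np.full((nr, nc), np.nan)
    cat = np.full((nr, nc), -1, dtype=int)
    for i in range(nr):
        for j in range(nc):
            xa, xd = a[:, i, j], d[:, i, j]
            ok = np.isfinite(xa) & np.isfinite(xd)
            if ok.sum() < 3 or np.std(xa[ok]) == 0 or np.std(xd[ok]) == 0:
                continue
            r[i, j], p[i, j] = pearson_with_test(xa[ok], xd[ok])
            cat[i, j] = CORRELATION_CATEGORIES.index(
                categorize_correlation(r[i, j], p[i, j], alpha))
    return {"r": r, "p": p, "category": cat}


def per_type_correlation(agb_annual: GridStack, driver_annual: GridStack,
                         type_map: TypeMap) -> pd.DataFrame:
    """Correlate type-mean AGB and driver series for each grassland type.

    The spatial mean over the type's pixels is taken first, then the temporal
    Pearson correlation; types with no pixels are skipped with a warning.
    """
    rows = []
    a = agb_annual.data_nan()
    d = driver_annual.data_nan()
    for code in type_map.present_codes():
        sel = type_map.codes == code
        if sel.sum() < 1:
            warnings.warn(f"type code {code} has no pixels; skipped", stacklevel=2)
            continue
        a_series = np.nanmean(a[:, sel], axis=1)
        d_series = np.nanmean(d[:, sel], axis=1)
        ok = np.isfinite(a_series) & np.isfinite(d_series)
        if ok.sum() < 3 or np.std(a_series[ok]) == 0 or np.std(d_series[ok]) == 0:
            warnings.warn(f"type code {code} has a degenerate series; skipped",
                          stacklevel=2)
            continue
        r, p = pearson_with_test(a_series[ok], d_series[ok])
        rows.append({"code": code, "name": type_map.legend.get(code, str(code)),
                     "n_pixels": int(sel.sum()), "r": r, "p": p})
    return pd.DataFrame(rows)


def build_driver_table(agb_annual: GridStack,
                       drivers: dict[str, GridStack],
                       unit: str = "pixel") -> pd.DataFrame:
    """Design table for the random forest.

    ``unit="pixel"`` (default): one row per pixel, temporal means over the
    study period.  ``unit="pixel-year"``: one row per pixel-year.
    """
    missing = [d for d in DRIVERS if d not in drivers]
    if missing:
        raise ValueError(f"missing driver stacks: {missing}")
    a = agb_annual.data_nan()
    cols = {}
    if unit == "pixel":
        cols["AGB"] = np.nanmean(a, axis=0).ravel()
        for name in DRIVERS:
            cols[name] = np.nanmean(drivers[name].data_nan(), axis=0).ravel()
    elif unit == "pixel-year":
        cols["AGB"] = a.reshape(a.shape[0], -1).ravel()
        for name in DRIVERS:
            v = drivers[name].data_nan()
            cols[name] = v.reshape(v.shape[0], -1).ravel()
    else:
        raise ValueError(f"unknown sampling unit {unit!r}")
    return pd.DataFrame(cols)


def rf_importance(table: pd.DataFrame, n_trees: int = 1000, seed: int = 0,
                  min_rows: int = 50, n_repeats: int = 5) -> ImportanceResult:
    """Random-forest relative importance of the seven drivers, in percent.

    Fits a random-forest regression of AGB on the drivers and computes seeded
    permutation importance; negative raw importances are floored at 0 and the
    vector is normalised to sum to 100.  Rows with any missing cell are
    dropped and counted.
    """
    cols = list(DRIVERS) + ["AGB"]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"driver table missing columns: {missing}")
    clean = table[cols].dropna()
    n_dropped = len(table) - len(clean)
    if len(clean) < min_rows:
        raise ValueError(f"need at least {min_rows} complete rows; "
                         f"got {len(clean)}")
    x = clean[list(DRIVERS)].to_numpy()
    y = clean["AGB"].to_numpy()
    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed,
                               n_jobs=1)
    rf.fit(x, y)
    perm = permutation_importance(rf, x, y, n_repeats=n_repeats,
                                  random_state=seed, n_jobs=1)
    raw = np.maximum(perm.importances_mean, 0.0)
    if raw.sum() == 0:
        shares = np.full(len(DRIVERS), 100.0 / len(DRIVERS))
    else:
        shares = 100.0 * raw / raw.sum()
    return ImportanceResult(shares=dict(zip(DRIVERS, shares.tolist())),
                            n_trees=n_trees, seed=seed,
                            n_rows_used=len(clean), n_rows_dropped=n_dropped)
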