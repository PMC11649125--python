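"""NPP-to-biomass allocation and grazing-intensity estimation.

Net primary production (g C/m²) is partitioned between shoots and roots with
per-type root:shoot ratios and layer-specific carbon fractions, yielding
aboveground biomass (AGB, g dry matter/m²) and its carbon density.  Grazing
intensity (GI) is inferred from the gap between aboveground production and
standing biomass divided by per-animal intake, expressed in standard livestock
units per unit area.

Two algebraic readings of the allocation rule are provided behind a strategy
switch; ``carbon_partition`` (the default) is the one that conserves carbon:

    NPP = Ca·AGB + Cb·BGB,  BGB = (R/S)·AGB
    ⇒ AGB = NPP / (Ca + (R/S)·Cb),  ANPP = Ca·AGB

The alternative ``literal`` strategy reads the rule as
AGB = ANPP / [(R/S)·(Ca + Cb)] with ANPP = NPP/(1 + R/S).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import GridStack, TypeMap

#: Carbon fraction of aboveground dry matter used for AGB carbon density.
AGB_CARBON_COEF = 0.45


@dataclass(frozen=True)
class TypeAllocation:
    rs_ratio: float
    c_a: float
    c_b: float

    def __post_init__(self) -> None:
        if self.rs_ratio <= 0:
            raise ValueError("rs_ratio must be > 0")
        if not (0 < self.c_a < 1 and 0 < self.c_b < 1):
            raise ValueError("carbon fractions must lie in (0, 1)")


@dataclass
class AllocationParams:
    """Per-grassland-type R/S and carbon-fraction table keyed by class code."""

    table: dict[int, TypeAllocation] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "AllocationParams":
        with resources.files("agbpipe.data").joinpath(
                "allocation_table1.csv").open() as fh:
            return cls.from_csv(fh)

    @classmethod
    def from_csv(cls, path_or_buf) -> "AllocationParams":
        df = pd.read_csv(path_or_buf)
        table = {int(r.code): TypeAllocation(float(r.rs_ratio), float(r.c_a),
                                             float(r.c_b))
                 for r in df.itertuples()}
        return cls(table)

    def __getitem__(self, code: int) -> TypeAllocation:
        try:
            return self.table[int(code)]
        except KeyError:
            raise KeyError(f"no allocation parameters for class code {code}") from None


@dataclass(frozen=True)
class GrazingParams:
    """Daily dry-matter intake P (g/day per livestock unit) and grazing days T."""

    daily_intake_p: float = 1800.0
    grazing_days_t: float = 365.0

    def __post_init__(self) -> None:
        if self.daily_intake_p <= 0 or self.grazing_days_t <= 0:
            raise ValueError("grazing parameters must be positive")


@dataclass
class AgbField:
    agb: GridStack           # g dry matter / m²
    anpp: GridStack          # g C / m²
    agb_carbon: GridStack    # g C / m²
    strategy: str


def _per_pixel_params(type_map: TypeMap, params: AllocationParams
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    codes = type_map.codes
    rs = np.zeros(codes.shape)
    ca = np.full(codes.shape, np.nan)
    cb = np.full(codes.shape, np.nan)
    for code in type_map.present_codes():
        p = params[code]
        sel = codes == code
        rs[sel], ca[sel], cb[sel] = p.rs_ratio, p.c_a, p.c_b
    return rs, ca, cb


def npp_to_agb(npp: GridStack, type_map: TypeMap,
               params: AllocationParams | None = None,
               strategy: str = "carbon_partition") -> AgbField:
    """Convert an NPP stack (g C/m²) to aboveground biomass per pixel.

    ``carbon_partition`` splits production carbon by the root:shoot biomass
    ratio with layer carbon fractions; ``literal`` applies the alternative
    reading documented in the module docstring.
    """
    if params is None:
        params = AllocationParams.default()
    if strategy not in ("carbon_partition", "literal"):
        raise ValueError(f"unknown allocation strategy: {strategy!r}")
    if type_map.grid_shape != npp.grid_shape:
        raise ValueError("type map and NPP grids are misaligned")

    rs, ca, cb = _per_pixel_params(type_map, params)
    off = type_map.codes == 0
    vals = npp.data_nan()
    if strategy == "carbon_partition":
        agb = vals / (ca + rs * cb)
        anpp = ca * agb
    else:
        anpp = vals / (1.0 + rs)
        agb = anpp / (rs * (ca + cb))
    agb[:, off] = np.nan
    anpp[:, off] = np.nan
    mask = ~np.isfinite(agb)
    agb_stack = npp.like(agb, mask, units="g/m2")
    anpp_stack = npp.like(anpp, mask.copy(), units="gC/m2")
    return AgbField(agb=agb_stack, anpp=anpp_stack,
                    agb_carbon=agb_to_carbon(agb_stack), strategy=strategy)


def agb_to_carbon(agb: GridStack) -> GridStack:
    """Carbon density of aboveground biomass: 0.45 g C per g dry matter."""
    return agb.like(AGB_CARBON_COEF * agb.data_nan(), agb.mask.copy(),
                    units="gC/m2")


def compute_gi(anpp_t: GridStack, agb_t: GridStack,
               gp: GrazingParams | None = None
               ) -> tuple[GridStack, np.ndarray]:
    """Grazing intensity GI = (ANPP_t − AGB_t)/(P·T), livestock units per m².

    Negative values (standing biomass exceeding production) have no livestock
    interpretation; they are floored at 0 and flagged.  Returns the GI stack
    and a boolean flag array marking floored cells.  Multiply by 1e4 for
    units/ha.
    """
    gp = gp or GrazingParams()
    if anpp_t.shape != agb_t.shape:
        raise ValueError("ANPP and AGB stacks are misaligned")
    denom = gp.daily_intake_p * gp.grazing_days_t
    gi = (anpp_t.data_nan() - agb_t.data_nan()) / denom
    flagged = np.isfinite(gi) & (gi < 0)
    gi = np.where(flagged, 0.0, gi)
    return anpp_t.like(gi, ~np.isfinite(gi), units="LSU/m2"), flagged


def gi_per_hectare(gi: GridStack) -> GridStack:
    return gi.like(gi.data_nan() * 1e4, gi.mask.copy(), units="LSU/ha")
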