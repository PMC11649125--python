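"""Per-pixel biomass trends and interannual stability.

Theil-Sen slope with Mann-Kendall significance classifies each pixel into
five improvement/degradation classes (stable band ±0.5 g/m²/yr, α=0.05);
the coefficient of variation classifies stability into five quantile
levels.  Also demonstrates recovery of a known injected trend.
"""

import numpy as np
import pandas as pd

from agbpipe import synthio, trends

OUT = "results/analysis"

# trend recovery on a scenario with a known slope
scen = synthio.SyntheticScenario(n_years=35, grid_shape=(20, 20),
                                 agb_trend=1.0, noise_sd={"AGB": 10.0}, seed=2)
_, truth = synthio.generate_scenario(scen)
tr = trends.trend_stack(truth.agb_true)
cv = trends.cv_stack(truth.agb_true)

trend_pct = trends.area_fraction(tr["category"], trends.TREND_CATEGORIES)
cv_pct = trends.area_fraction(cv["level"], trends.CV_LEVELS)
pd.DataFrame([trend_pct]).to_csv(f"{OUT}/trend_area_pct.csv", index=False)
pd.DataFrame([cv_pct]).to_csv(f"{OUT}/cv_area_pct.csv", index=False)

med = float(np.nanmedian(tr["slope"]))
power = float((tr["p"] < 0.05).mean())
print(f"injected slope 1.0 g/m2/yr; pixel-median Theil-Sen slope {med:.3f}")
print(f"Mann-Kendall flags {100 * power:.1f}% of pixels at alpha=0.05")
print("trend classes (% of area):",
      {k: round(v, 2) for k, v in trend_pct.items()})
print("stability levels (% of area):",
      {k: round(v, 2) for k, v in cv_pct.items()})
print("a 1 g/m2/yr improvement against 10 g/m2 noise is recovered almost "
      "everywhere over 35 years")
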