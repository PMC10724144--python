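"""WHO short-term exposure risk on the retrieved PM2.5 field.

Counts, per cell, days strictly above the daily guideline (15 ug/m3) and
interim targets (25/37.5/50/75), reports the fraction of populated area
(density > 1 km^-2) exposed for at least 1/7/30 days per threshold, and
per-country population-weighted means.  Writes results/exposure_summary.json
and results/exposure_by_country.csv.
"""

import numpy as np
import pandas as pd

from common import RESULTS, SCRATCH, get_world, save_json
from gaplesspm import aod_gapfill
from gaplesspm.health_impact import (
    ThresholdSet,
    exceedance_days_grid,
    populated_area_fractions,
    population_weighted_mean,
)
from gaplesspm.synthworld import cell_area_km2


def main():
    world = get_world()
    pm_field, _ = aod_gapfill.read_field(SCRATCH / "pm25_gapless.nc")
    cube = pm_field.values
    thresholds = ThresholdSet()
    pop = world.static["population"]
    density = pop / cell_area_km2(world.grid)

    exceed = {name: exceedance_days_grid(cube, level)
              for name, level in thresholds.as_ladder().items()}
    fractions = populated_area_fractions(exceed, density)
    print("populated-area fractions (% of populated cells):")
    for name in ("aqg", "it4", "it3", "it2", "it1"):
        f = fractions[name]
        print(f"  {name.upper():>4s} >= 1/7/30 days: "
              f"{f[1]:.0f}% / {f[7]:.0f}% / {f[30]:.0f}%")

    country = world.regions.pivot(index="cell_i", columns="cell_j",
                                  values="country").to_numpy()
    rows = []
    for c in np.unique(country):
        mask = country == c
        pwm = population_weighted_mean(cube.mean(axis=0), pop, mask)
        days_aqg = exceed["aqg"][mask]
        rows.append({
            "country": c,
            "pwm_pm25": pwm,
            "mean_days_above_aqg": float(days_aqg.mean()),
            "pct_cells_any_aqg_exceedance": 100.0 * float((days_aqg > 0).mean()),
        })
    by_country = pd.DataFrame(rows).sort_values("pwm_pm25", ascending=False)
    by_country.to_csv(RESULTS / "exposure_by_country.csv", index=False)

    global_pwm = population_weighted_mean(cube.mean(axis=0), pop)
    save_json(
        {
            "global_population_weighted_pm25": global_pwm,
            "populated_area_fractions_percent": fractions,
            "most_exposed_country": by_country.iloc[0]["country"],
        },
        "exposure_summary.json",
    )
    print(f"global population-weighted PM2.5: {global_pwm:.1f} ug/m3; "
          f"most exposed country {by_country.iloc[0]['country']} "
          f"({by_country.iloc[0]['pwm_pm25']:.1f} ug/m3)")
    print(f"tables -> {RESULTS / 'exposure_by_country.csv'}")


if __name__ == "__main__":
    main()
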