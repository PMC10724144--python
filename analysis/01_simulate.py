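"""Generate the synthetic world all later analyses run on.

The world stands in for a year of satellite AOD retrievals, CTM fields,
meteorology, static covariates, an uneven hourly station network (with
injected outliers), stringency indices, and baseline mortality rates.
Writes a structure summary to results/world_summary.json; the bundle itself
is cached under scratch/.
"""

import numpy as np

from common import WORLD_CONFIG, get_world, save_json


def main():
    world = get_world()
    cfg = WORLD_CONFIG
    summary = {
        "grid": [cfg.n_lat, cfg.n_lon],
        "cell_deg": cfg.cell_deg,
        "n_days": cfg.n_days,
        "n_stations": cfg.n_stations,
        "n_countries": cfg.n_countries,
        "aod_missing_fraction": float(world.cloud_mask.mean()),
        "pm25_mean": float(world.true_pm25.mean()),
        "pm25_p95": float(np.quantile(world.true_pm25, 0.95)),
        "station_hourly_rows": int(len(world.station_hourly)),
        "injected_outliers": world.outlier_log["kind"].value_counts().to_dict(),
    }
    path = save_json(summary, "world_summary.json")
    print(f"world: {cfg.n_lat}x{cfg.n_lon} cells x {cfg.n_days} days, "
          f"{cfg.n_stations} stations in {cfg.n_countries} countries")
    print(f"AOD missingness {summary['aod_missing_fraction']:.1%} "
          f"(target {cfg.missing_frac:.0%}); "
          f"PM2.5 mean {summary['pm25_mean']:.1f} ug/m3")
    print(f"summary -> {path}")


if __name__ == "__main__":
    main()
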