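"""Quality-control the hourly station records and aggregate to daily means.

Removes negatives, stuck repeats (>3 continuous identical hours), and
per-station 99.9th-percentile extremes, then keeps days with >= 20% valid
hours.  Because the generator logged every injected outlier, recall is
measurable exactly.  Writes results/qc_summary.json and caches the daily
table under scratch/.
"""

from common import SCRATCH, get_world, save_json
from gaplesspm import station_qc


def main():
    world = get_world()
    hourly = world.station_hourly
    cleaned = station_qc.qc_hourly(hourly)
    daily = station_qc.daily_mean(cleaned)

    key = cleaned.set_index(["station_id", "datetime_utc"])["pm25"]
    recall = {}
    for kind, sub in world.outlier_log.groupby("kind"):
        vals = key.loc[list(zip(sub["station_id"], sub["datetime_utc"]))]
        recall[kind] = float(vals.isna().mean())

    n_removed = int(cleaned["pm25"].isna().sum() - hourly["pm25"].isna().sum())
    summary = {
        "hourly_rows": int(len(hourly)),
        "hourly_values_removed": n_removed,
        "removed_fraction": n_removed / len(hourly),
        "outlier_recall": recall,
        "station_days_emitted": int(len(daily)),
        "station_days_possible": int(world.config.n_stations
                                     * world.config.n_days),
    }
    daily.to_csv(SCRATCH / "daily_station_pm25.csv", index=False)
    path = save_json(summary, "qc_summary.json")
    print(f"QC removed {n_removed} of {len(hourly)} hourly values "
          f"({summary['removed_fraction']:.2%})")
    print("injected-outlier recall: "
          + ", ".join(f"{k}={v:.1%}" for k, v in recall.items()))
    print(f"{len(daily)} station-days passed the 20% completeness rule; "
          f"summary -> {path}")


if __name__ == "__main__":
    main()
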