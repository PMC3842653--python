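#!/usr/bin/env python
"""Generate the default synthetic study season and summarize its structure.

Writes the raw tables (counts, covariates, demographics, station network)
and a descriptive-statistics table per region — the synthetic analogue of
the study's data summary: 121 days, six sub-regions, episodic heavy-tailed
fire PM, low anthropogenic PM2.5, seasonal weather, fixed demographics.
"""

import sys
from pathlib import Path

import pandas as pd

from firegam.io import write_counts, write_covariates, write_demographics, write_stations, write_zips
from firegam.synth import SyntheticConfig, simulate_dataset

OUT = Path("results/analysis")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(SyntheticConfig(seed=SEED), with_stations=True)
    write_counts(ds["counts"], OUT / "counts.csv")
    write_covariates(ds["covariates"], OUT / "covariates.csv")
    write_demographics(ds["demographics"], OUT / "demographics.csv")
    write_stations(ds["station_weather"], OUT / "stations.csv")
    write_zips(ds["zips"], OUT / "zips.csv")

    cov = ds["covariates"].merge(ds["counts"], on=["region_id", "date"])
    rows = []
    for region, g in cov.groupby("region_id"):
        rows.append(
            {
                "region": region,
                "visits_mean": g["visits"].mean(),
                "visits_sd": g["visits"].std(),
                "fire_pm10_mean": g["fire_pm10"].mean(),
                "fire_pm10_sd": g["fire_pm10"].std(),
                "fire_pm10_max": g["fire_pm10"].max(),
                "anthro_pm25_mean": g["anthro_pm25"].mean(),
                "mean_rh_mean": g["mean_rh"].mean(),
                "min_temp_mean": g["min_temp"].mean(),
                "population": int(g["population"].iloc[0]),
            }
        )
    desc = pd.DataFrame(rows).round(2)
    desc.to_csv(OUT / "descriptive_stats.csv", index=False)
    print(f"seed {SEED}: wrote {len(cov)} region-days for {cov['region_id'].nunique()} regions")
    print(desc.to_string(index=False))
    print("\nHeavy-tailed fire PM: county-scale mean ~12 ug/m3 with maxima in the "
          "hundreds; daily visit means track the configured regional levels.")


if __name__ == "__main__":
    main()
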