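"""Light-level geolocation accuracy against simulator truth.

Compares calibrated, smoothed daily position estimates with the true
track, away from equinoxes, and reports the calibration angles selected
per bird-year (the generator crosses the 10-unit threshold at -4 deg).
"""

import pandas as pd

from _config import PIPELINE_DIR, RESULTS, run

result = run()
pos = pd.read_csv(PIPELINE_DIR / "positions.csv", parse_dates=["date"])
truth = pd.read_csv(PIPELINE_DIR / "truth_positions.csv", parse_dates=["date"])

merged = pos[pos["valid"] & (pos["days_from_equinox"] > 15)].merge(
    truth, on=["bird", "year", "date"], suffixes=("_est", "_true"))
lat_err = (merged["latitude_est"] - merged["latitude_true"]).abs()
lon_err = (merged["longitude_est"] - merged["longitude_true"]).abs()

print(f"valid daily positions compared: {len(merged)}")
print(f"median |latitude error|:  {lat_err.median():.3f} deg")
print(f"median |longitude error|: {lon_err.median():.3f} deg")
angles = pos.groupby(["bird", "year"])["angle"].first()
print("calibrated sun elevation angles:",
      dict(angles.value_counts()))

table = pd.DataFrame({"median_lat_err": [lat_err.median()],
                      "median_lon_err": [lon_err.median()],
                      "p90_lat_err": [lat_err.quantile(0.9)],
                      "n": [len(merged)]})
table.to_csv(RESULTS / "02_geolocation_error.csv", index=False)
print(f"wrote {RESULTS / '02_geolocation_error.csv'}")
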