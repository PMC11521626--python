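"""Migration phenology recovered from estimated longitudes.

Compares run-length-rule dates (southbound start, northbound start,
colony return) with the simulator's true dates.
"""

import pandas as pd

from _config import PIPELINE_DIR, RESULTS, run

result = run()
det = pd.read_csv(PIPELINE_DIR / "phenology.csv",
                  parse_dates=["southbound_start", "northbound_start", "northbound_end"])
truth = pd.read_csv(PIPELINE_DIR / "truth_phenology.csv",
                    parse_dates=["southbound_start", "northbound_start", "northbound_end"])

m = det.merge(truth, on=["bird", "year"], suffixes=("_det", "_true"))
rows = []
for key in ("southbound_start", "northbound_start", "northbound_end"):
    err = (m[f"{key}_det"] - m[f"{key}_true"]).abs() / pd.Timedelta(days=1)
    rows.append({"date": key, "median_abs_err_days": err.median(),
                 "max_abs_err_days": err.max(), "n": err.notna().sum()})
    print(f"{key:18s} median |err| {err.median():.1f} d, max {err.max():.1f} d")
pd.DataFrame(rows).to_csv(RESULTS / "04_phenology_error.csv", index=False)
print(f"wrote {RESULTS / '04_phenology_error.csv'}")
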