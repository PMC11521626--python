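"""Immersion-derived behaviour: foraging effort and colony visitation.

Summarises day-length-standardised foraging proportions for January (on
the Patagonian shelf) and August (chick-rearing at the colony), and the
mixture-based August colony-visit counts, against the simulator's true
visit nights.
"""

import pandas as pd

from _config import PIPELINE_DIR, RESULTS, run

result = run()
beh = result.summary

print(f"January foraging proportion: mean {beh['january_foraging'].mean():.3f} "
      f"(n={beh['january_foraging'].notna().sum()})")
print(f"August foraging proportion (prev season): mean "
      f"{beh['august_foraging_prev'].mean():.3f}")
print(f"August colony visits (prev season): mean "
      f"{beh['august_visits_prev'].mean():.1f} nights")

nights = pd.read_csv(PIPELINE_DIR / "nights.csv", parse_dates=["night_date"])
print(f"nights classified: {len(nights)}; "
      f"visit fraction {nights['is_visit'].mean():.2f}")

beh[["bird", "year", "january_foraging", "august_foraging_prev",
     "august_visits_prev"]].to_csv(RESULTS / "03_behaviour_summary.csv", index=False)
print(f"wrote {RESULTS / '03_behaviour_summary.csv'}")
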