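"""Season calendar, altitude-adjusted anaemia grading, winsorizing.

The agropastoral year splits into arduous (harvest + planting, 129 days) and
better (237 days) periods; anaemia at 3800 m uses the upward-shifted
14.6 g/dl cut-off.
"""

import numpy as np

from alticycle import (
    DEFAULT_ANAEMIA_CUTOFFS,
    assign_season,
    classify_anaemia,
    season_day_totals,
    winsorize,
)

arduous, better = season_day_totals()
print(f"arduous days: {arduous}, better days: {better} (sum {arduous + better})")
for day in (1, 91, 92, 244, 245, 282, 283, 366):
    print(f"  day {day:3d} -> {assign_season(day)}")

print(f"\nanaemia threshold: {DEFAULT_ANAEMIA_CUTOFFS.anaemia_threshold} g/dl")
for hb in (16.2, 14.6, 14.0, 12.0, 9.5):
    print(f"  hb {hb:5.1f} g/dl -> {classify_anaemia(hb)}")

rng = np.random.default_rng(0)
hb = np.concatenate([rng.normal(15.5, 1.0, 148), [9.3, 9.8, 20.1, 19.5]])
capped, lo, hi = winsorize(hb, 5, 95)
print(f"\nwinsorize caps (5th/95th centiles): {lo:.2f} / {hi:.2f} g/dl; "
      f"{np.sum(capped != hb)} of {hb.size} values recoded")
# Capping keeps outlying cycles in the analysis at the centile values instead
# of dropping them.
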