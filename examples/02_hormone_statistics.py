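"""Mean peak luteal progesterone from an every-other-day salivary series.

Builds one ovulatory-looking cycle, finds the observed luteal peak, averages
the linear interpolant over the ±2.5-day window around it (AUC / width) and
classifies ovulation by threshold.
"""

from alticycle import HormoneSeries, classify_ovulation, mean_peak_luteal_p4

days = [1, 3, 5, 7, 9, 11, 13, 15, 17, 19, 21, 23, 25, 27]
p4 = [48, 52, 45, 50, 55, 62, 85, 130, 190, 240, 255, 205, 130, 75]  # pmol/l
series = HormoneSeries.from_arrays(days, p4, cycle_length=28)

res = mean_peak_luteal_p4(series)  # luteal search window: cycle midpoint .. last day
print(f"observed luteal peak on day {res.peak_day:g}")
print(f"averaging window: [{res.window_start:g}, {res.window_end:g}] days, "
      f"coverage {res.coverage_fraction:.0%}")
print(f"mean peak luteal P4: {res.mpl_p4:.1f} pmol/l")
print("ovulatory at 100 pmol/l threshold:",
      bool(classify_ovulation(res.mpl_p4, threshold=100.0)))
# The statistic averages around the *observed* peak, so cycles whose luteal
# rise comes early or late are measured where their peak actually is.
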