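# Study analysis configuration.
#
# ovul_threshold (pmol/l): the ovulation cut-off on mean peak luteal
# progesterone.  The numeric value used by the original field study lives in
# a prior publication and is not restated in the analysis we reproduce; the
# 100 pmol/l shipped here is an ASSUMPTION chosen to sit between the
# anovulatory baseline and ovulatory luteal levels of salivary P4.  Replace
# it with the assay-specific published cut-off before analysing real data.
#
# Anaemia severity bounds: only the 14.6 g/dl altitude-adjusted anaemia
# threshold is published for this population; the mild/moderate bounds apply
# the same +2.6 g/dl altitude shift to the standard sea-level severity bands
# and are likewise an assumption, not a published value.
cycles_csv: null
samples_csv: null
output_dir: results
calendar:
  arduous_ranges: [[1, 91], [245, 282]]      # harvesting; planting
  better_ranges: [[92, 136], [137, 244], [283, 366]]
  year_length: 366
cutoffs:
  anaemia_threshold: 14.6
  mild_lower: 13.6
  moderate_lower: 10.6
ovul_threshold: 100.0
winsor_lo_pct: 5.0
winsor_hi_pct: 95.0
min_peak_coverage: 0.5
imputation_m: 5
imputation_max_iter: 10
imputation_k_donors: 5
imputation_seed: 20240912
imputable_columns: [trad_econ, body_fat]
imputation_predictors: [hb, age, breastfeeding]
scale_within_stratum: false
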