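# Synthetic study generator configuration.
# Defaults emulate the study design: 96 women contributing 1/2/3 cycles
# (48/40/8 women -> 152 cycles), ~34/152 cycles in arduous seasons, a
# 0.76 g/dl arduous-season haemoglobin drop concentrated in
# high-traditional-economy households, and an haemoglobin effect on
# ovulation odds (OR 3 per SD) in arduous seasons only.
n_women: 96
cycles_per_woman_counts: [48, 40, 8]
p_arduous: 0.2236842105263158          # 34/152
hb_mean: 15.7                          # better-season mean, g/dl
hb_sd: 0.9                             # residual SD, g/dl
beta_season_hb: 0.76                   # arduous-season drop, g/dl
beta_trad_arduous: -0.42               # g/dl per SD trad-econ, arduous only
sigma_u_hb: 0.8
logit_intercept: 1.3
beta_hb_ovul_arduous: 1.0986122886681098   # log(3)
beta_hb_ovul_better: 0.0
sigma_u_ovul: 1.0
p4_baseline: 50.0                      # pmol/l
p4_luteal_peak: 250.0                  # pmol/l
p4_noise_cv: 0.25
ovul_threshold: 100.0                  # pmol/l
missing_rate_trad: 0.15789473684210525 # 24/152
prob_breastfeeding: 0.48026315789473684
seed: 20240912
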