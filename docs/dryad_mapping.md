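# Mapping the Dryad deposit to the `alticycle` schema

The original study's data are deposited at Dryad
(doi:10.5061/dryad.tqjq2bw7f). They are **never required** to build or test
this package — every test runs on synthetic data — but users who obtain the
deposit can analyse it by reshaping it into the two-file CSV layout below.
This is a recipe, not an ingester: deposit layouts change, and silent
automatic mapping of a third-party archive is how column mix-ups happen.

## Target layout

`cycles.csv` — one row per menstrual cycle:

| column          | unit / coding                               |
|-----------------|---------------------------------------------|
| woman_id        | participant identifier (string)             |
| cycle_index     | 1, 2, 3 within woman                        |
| hb              | haemoglobin, g/dl (uncapped; the pipeline winsorizes) |
| hb_day_of_year  | 1–366, day of the haemoglobin visit         |
| age             | years                                       |
| breastfeeding   | 1 = breastfeeding and menstruating, 0 = menstruating only |
| trad_econ       | household traditional-economy factor score; blank if missing |
| body_fat        | anthropometric body-fat factor score; blank if missing |
| cycle_length    | days, integer; blank if unknown             |

`p4_samples.csv` — one row per saliva sample:

| column      | unit / coding                          |
|-------------|----------------------------------------|
| woman_id    | as above                               |
| cycle_index | as above                               |
| day         | day in cycle, day 1 = first menses day |
| p4_pmol_l   | salivary progesterone, pmol/l          |

## Recipe

1. Exclude cycles coded as pregnant, cycles with confirmed or possible
   early pregnancy loss, and cycles lacking haemoglobin, ovulation or
   progesterone data — the analytic sample is defined on complete outcome
   data, with covariate missingness handled by imputation, not exclusion.
2. Where a cycle has two haemoglobin measures, keep the one taken latest in
   the cycle.
3. Convert the haemoglobin visit date to a 1–366 day of year (leap-year
   numbering).
4. If the deposit provides anthropometric raw measures rather than a
   body-fat score, compute the score with
   `alticycle.ecology.body_fat_score` on the complete measurement matrix
   (impute first if needed).
5. Write the two CSVs and run
   `alticycle analyze --cycles cycles.csv --samples p4_samples.csv
   --config configs/study_config.yaml`, after replacing the assumed
   `ovul_threshold` with the published assay-specific cut-off.

Expected checks against the published analysis are recorded in
`alticycle.pipeline.DRYAD_REFERENCE_TARGETS` (e.g. winsorize caps near
11.8/17.5 g/dl, median hb 15.6 g/dl). Exact replication of the regression
tables additionally requires the original random-forest imputation stream,
so close — not bitwise — agreement is the realistic goal.
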