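# File formats

Every file written by `rdipw` is UTF-8 CSV with a header row, preceded by a
one-line versioned schema comment (`# rdipw <kind> v1`). Missing values are
empty fields. All times are in months from entry into care (period index ×
period length; the default period is one month).

## cohort (`# rdipw cohort v1`)

One row per subject.

| column | type | meaning |
|---|---|---|
| subject_id | int | stable identifier |
| baseline_cd4 | float | assignment variable, cells/μL (0.1 resolution) |
| age | float | years at entry |
| sex | str | `female` / `male` |
| education | str | `<=7` / `8-12` / `>12` / `missing` |
| wealth_quintile | float | 1–5 from the asset PCA, empty if missing |
| distance_km | float | distance to clinic |
| residence | str | `rural` / `periurban` / `urban` / `missing` |
| entry_time | int | period index of entry (always 0) |
| art_init_time | float | period index of ART initiation, empty if never |
| lab_times | str | `;`-separated period indices with a recorded lab |
| lab_cd4 | str | `;`-separated CD4 values matching `lab_times` |
| event_time | float | period index of death, empty if alive |
| followup_end | int | last observed period index |
| asset_00 … | float | binary asset indicators, empty row if battery missing |

## truth (`# rdipw truth v1`)

| column | meaning |
|---|---|
| subject_id | as above |
| compliance_class | `always` / `complier` / `never` |
| baseline_rate | per-period untreated event rate at the subject's CD4 |
| true_log_hr | conditional log hazard ratio used in generation |

## person-period (`# rdipw person-period v1`)

One row per subject per period at risk. Carries `subject_id`, `period`,
`period_start`/`period_stop` (months), `at_risk`, `event`, `eligible`,
`art_now` (time-varying), `art_immediate` (grace-period definition),
`current_cd4` (last recorded lab carried forward), `last_lab_time`,
`censored_this_period`, and the baseline covariates repeated per row.

## weights (`# rdipw weights v1`)

`subject_id`, `period`, `treatment_weight`, `censoring_weight`,
`combined_weight` (the row-wise product).

## fit reports (`# rdipw fit v1`)

Tab-separated `key<TAB>value` lines: model tag, window/form/link, n,
events, `hr`, `ci95_low`, `ci95_high`, leading coefficients, and
first-stage/CACE entries where applicable.
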