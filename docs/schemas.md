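# File schemas

All artifacts are plain UTF-8 CSV with `.` decimals, accompanied by a
JSON sidecar `<name>.csv.meta.json` carrying `schema_version` (currently
`"1.0"`), the generating seed and enough parameters to regenerate the
file.  A schema-version mismatch on read is a hard error.

## Categorical codes

| column | values |
|---|---|
| `sex` | `male`, `female` |
| `age_group` | `<1`, `1-2`, `3-4`, `5-9`, `10-14`, ... 5-year bands ... `90-94`, `95+` (22 bands) |
| `education` | `<6y`, `6-<12y`, `>=12y` |
| `urbanicity` | `urban`, `rural` |
| `method` | `24hr_recall`, `FFQ`, `DHS`, `HBS` |

The sentinel `all` in `sex`/`age_group`/`education`/`urbanicity` marks a
dimension the survey did not stratify (a collapsed cell).

## surveys.csv

One row per survey-stratum-factor observation.

| column | type | meaning |
|---|---|---|
| `survey_id` | str | unique survey identifier |
| `country` | str | country code |
| `year` | int | survey midpoint year |
| `method` | str | dietary assessment method |
| `representative` | bool | nationally representative sample |
| `sex`, `age_group`, `education`, `urbanicity` | str | stratum (or `all`) |
| `factor` | str | dietary factor name |
| `observed_mean` | float > 0 | sample mean intake, natural units |
| `observed_sd` | float >= 0 | sample SD of individual intakes |
| `n` | int >= 1 | participants behind the cell |

## weights.csv

| column | type |
|---|---|
| `country`, `year` | str, int |
| `sex`, `age_group`, `education`, `urbanicity` | str (full 264-cell coverage per country-year) |
| `persons` | float >= 0 |

## covariates.csv

`factor, country, year, value` — one country-year covariate value per
factor (the role food-availability series play for real intakes).

## Draw-level estimates (intakes, standardized intakes, scores)

Long format, draw order preserved:
`country, year, sex, age_group, education, urbanicity, factor` (or
`pattern`), `draw_id` (0..3999), `value`.  The sidecar records
`n_draws`; a file whose per-entity draw count disagrees is rejected on
read.  Draw `d` indexes the same joint posterior sample in every file of
a run — required for draw-wise differencing.

## Results tables

`scope, pattern, year, filter, median, ui_low, ui_high` — one row per
aggregate estimate; `filter` is a human-readable population restriction.

## Score definitions and cutpoints

Pattern definitions are YAML (`pattern`, `reference_year`, `rescale:
[num, den]`, `components: [{factor, direction, rule, worst?, optimal?}]`);
see `src/dietscore/data/*.yaml`.  Empirical cutpoints serialize via
`CutpointSet.to_dict()` as JSON/YAML with `quintiles` and `medians` maps
keyed `"<factor>|<sex>"`.
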