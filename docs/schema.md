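# Cohort interchange schema

One record per patient at KS diagnosis, plus outcome. Two on-disk formats
round-trip losslessly through `read_cohort` / `write_cohort`:

* **JSON** — an array of patient objects; lesions as a nested array, edema
  as a region → fraction map.
* **CSV** — one row per patient for scalars, with a companion long-format
  lesion table written alongside as `<stem>_lesions.csv`.

All enumerations serialize as lowercase snake-case strings, bit-exact.
Booleans serialize as `true`/`false` in CSV; missing optionals as empty
cells (CSV) or `null` (JSON).

## Patient scalars

| column | type | notes |
|---|---|---|
| `patient_id` | string | unique within a cohort |
| `age_years` | float | must be < 18 (pediatric cohort) |
| `on_cart_at_diagnosis` | bool | on combination antiretroviral therapy at KS diagnosis |
| `cd4_count_cells_per_uL` | float? | ≥ 0 when present |
| `cytopenia_grade` | enum | `none`, `mild`, `moderate_severe` |
| `lymph_node_involvement` | bool | |
| `visceral_pulmonary` | bool | clinical adjudication made upstream |
| `visceral_abdominal` | bool | clinical adjudication made upstream |
| `woody_edema` | bool | woody/non-pitting KS edema present |
| `facial_edema` | bool | stage-2 trigger, distinct from woody edema |
| `edema_frac_<region>` | float | fraction in [0, 1] of the region involved by woody edema; one column per Rule-of-9s region plus perineum |
| `widespread_distribution` | bool? | optional clinician override of the widespread rule |
| `regimen` | enum | `cart_only`, `bv`, `abv`, `paclitaxel` |
| `efs_time_months` | float | > 0 |
| `efs_event` | bool | induction failure, progression/relapse, or death |
| `os_time_months` | float | ≥ `efs_time_months` |
| `os_event` | bool | death, any cause |
| `cause_of_death` | enum | `ks`, `hiv_late_in_cr`, `hiv_early_oi`, `other`, `not_applicable` |

A death recorded at `efs_time_months == os_time_months` must carry
`efs_event = true` (death is itself an EFS event). `efs_time_months`
strictly before `os_time_months` with `efs_event = false` encodes EFS
censored at the last disease assessment before a later death.

## Lesion table (long format)

| column | type | notes |
|---|---|---|
| `patient_id` | string | joins to the scalar table |
| `lesion_type` | enum | `hyperpigmented_skin`, `flat_oral`, `nodular_oral`, `subcutaneous_nodule`, `conjunctival`, `exophytic_mass` |
| `region` | enum | 11 values: `head_neck`, `anterior_trunk`, `posterior_trunk`, `left_arm`, `right_arm`, `left_leg`, `right_leg`, `perineum`, `oral_cavity`, `conjunctiva`, `other` |
| `cluster_id` | string? | confluent-cluster label; all members share one region |
| `longest_diameter_mm` | float? | > 0 when present; used for response assessment |
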