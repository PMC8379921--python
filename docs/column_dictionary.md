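# Column dictionary

All tables are CSV with a header row, UTF-8, `.` decimal separator.
Positions are micrometres (µm), times are minutes, frames are 0-based
integers (minutes = frame × `frame_interval`). Signed long-axis positions
have their origin at the cell midpoint; the "low" end of a cell is the end
with the smaller global coordinate, and the "negative pole" is the low end.
Unknown columns in input tables are preserved, never dropped.

## cell_table.csv (one row per cell per frame)

| column        | type  | meaning                                                        |
|---------------|-------|----------------------------------------------------------------|
| `cell_id`     | int   | unique tracked-cell id                                         |
| `mother_id`   | int   | id of the mother cell; `-1` for cells with no observed mother  |
| `frame`       | int   | 0-based frame index                                            |
| `length_um`   | float | cell length along the long axis                                |
| `channel_id`  | int   | mother-machine channel / pad field id                          |
| `low_end_um`  | float | global coordinate of the low cell end (schematic after division) |
| `high_end_um` | float | global coordinate of the high cell end                         |

Daughters appear first at the mother's division frame (mother's last row is
the frame before). Global end coordinates are exact at division time (they
encode the septum position used for pole mapping); between divisions they are
schematic.

## focus_table.csv (one row per detected focus)

| column        | type  | meaning                                                        |
|---------------|-------|----------------------------------------------------------------|
| `cell_id`     | int   | cell the focus belongs to                                      |
| `frame`       | int   | frame index                                                    |
| `marker`      | str   | `L3`, `R3`, `ori1`, `ter3`, `dnaQ`, `dnaN`, `tsr`, `dapi`, `edu` |
| `position_um` | float | signed long-axis position in the cell frame, in [−L/2, +L/2]   |
| `intensity`   | float | arbitrary units; for `tsr` the polar accumulation readout      |

`tsr` rows come in pairs at the two cell poles. `dapi` marks nucleoid
centroids (one in B/C period, two in D period); `edu` foci appear only on
labeled nucleoids after `apply_edu_pulse_chase`. Same-marker foci closer
than the diffraction limit (`merge_radius`, default 0.3 µm) are reported as
one focus at their intensity-weighted mean.

## truth_table.csv (simulator ground truth, one row per cell per frame)

| column           | type | meaning                                                      |
|------------------|------|--------------------------------------------------------------|
| `cell_id`        | int  | cell id                                                      |
| `frame`          | int  | frame index                                                  |
| `phase`          | str  | cell-cycle period `B`, `C`, or `D`                           |
| `orientation`    | int  | arm orientation sign (+1: R3 toward the high end); 0 if n/a  |
| `config`         | str  | post-duplication arrangement `LRLR`/`RLRL`/`LRRL`/`RLLR`; empty before duplication |
| `flip`           | int  | 1 when an orientation flip occurred at this frame            |
| `pole_age_low`   | int  | generations since the low-end pole was created               |
| `pole_age_high`  | int  | generations since the high-end pole was created              |
| `anucleate`      | bool | cell carries no chromosome                                   |
| `binucleate`     | bool | cell born with two chromosomes (sister of an anucleate cell) |
| `ancestral_side` | int  | D period: cell half (+1 high / −1 low) holding the older-template chromosome; 0 otherwise |
| `edu_side`       | int  | D period after a pulse-chase: half with the EdU-labeled nucleoid (±1), 2 when both nucleoids are labeled, 0 otherwise |

## Pipeline outputs

* `division_records.csv` — `mother_id`, `frame`, `daughter_low`,
  `daughter_high`, `anucleate_daughter` (id or empty), `pole_side`
  (`old`/`new`/empty for unknown mother pole).
* `cycle_metrics.csv` — per complete cycle: `generation_time_min`,
  `birth_length_um`, `division_length_um`, ordered daughter birth lengths and
  their difference (`division_asymmetry_um`).
* `flip_probability_vs_length.csv` — `length_mid`, `n_frames` (eligible
  defined observations), `n_flips`, `probability` (per-observation hazard;
  empty bins have an empty probability, not 0).
* `dnaQ_dnaN_distances.csv` — per source focus: `cell_id`, `frame`,
  `source_pos`, `distance_um` to the nearest same-cell DnaN focus.
* `retention_calls.csv` — per cell: `older_pole`, `edu_nucleoid_pos`, `call`
  (`ANCESTRAL_AT_OLD_POLE` / `ANCESTRAL_AT_NEW_POLE` / `UNDETERMINED`).
* `demograph_L3R3.tsv` — per-length-bin max-normalized position × length
  count matrix.
* `summary.json` — headline statistics with sample sizes, standard errors and
  exclusion tallies; `manifest.json` — config hash, seed, package version,
  output SHA-256 hashes, timestamps.
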