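# chromolin

Single-cell lineage analytics for bacterial chromosome organization and
inheritance, together with a matched synthetic time-lapse simulator. The
package quantifies, from tidy tracked-cell and fluorescent-focus tables:

* **lineage** — division-forest construction, pole-age propagation,
  anucleate-division detection with old/new-pole attribution, origin-focus
  counting prior to division, generation-time and division-symmetry metrics;
* **organization** — per-cell orientation normalization, demographs with
  per-length-bin max normalization, L3–R3 arm distance, opposite-cell-half
  fraction, translational (LRLR/RLRL) vs mirror (LRRL/RLLR) sister-chromosome
  configuration calls;
* **flipping** — per-frame orientation traces with debounced flip detection,
  pre-duplication flips per cell cycle, flip probability vs cell length,
  mother→daughter configuration retention, post-duplication stability;
* **colocalization** — nearest-focus distances between marker pairs
  (e.g. DnaQ↔DnaN), colocalization fraction at the 300-nm diffraction limit,
  localization profiles and FWHM at selected cell lengths;
* **retention** — Tsr-intensity-based older-pole calls, EdU/DAPI nucleoid
  scoring, ancestral-strand retention fraction, binomial and two-proportion
  tests plus a between-replicate binomial-dispersion check;
* **stats** — Welch's t, pooled two-proportion z, two-tailed binomial test,
  and an empirical type-I-error calibration harness.

Because raw microscopy for this class of experiment is rarely deposited, the
package ships a first-class **simulator** (`chromolin.simulate`) that
generates seeded mother-machine and agarose-pad time-lapses (tracked cells,
foci, and ground truth) in two modes: *mechanistic*, where strand-level
bookkeeping, orientation-flip hazards, and translational/mirror segregation
make retention and configuration statistics emerge; and *phenomenological*,
where every observable is governed by a direct probability parameter so each
pipeline stage can be validated by parameter recovery. Strain parameter
bundles (`WT`, `dmukB`, `dmatP`, `matPdC20`, `dzapB`, `ddam`, `dseqA`) live in
`chromolin.presets`.

## Command line

```bash
# generate a synthetic dataset
chromolin simulate --preset dmatP --mode phenomenological --layout pad \
    --n-lineages 50 --duration 330 --seed 7 --out out_sim

# analyze existing tables, one or more stages
chromolin analyze --cell-table out_sim/cell_table.csv \
    --focus-table out_sim/focus_table.csv --stage flipping \
    --frame-interval 10 --out out_analysis

# full reproducible pipeline from a config file
chromolin run examples/demo_config.yaml --out out_demo
chromolin report out_demo
```

`chromolin run` simulates (or loads) the data, executes the configured stages
in dependency order, and writes per-stage CSV outputs, a `summary.json` of
headline statistics, and a `manifest.json` with content hashes — rerunning an
identical config reproduces identical hashes. See
`docs/column_dictionary.md` for every table schema and
`examples/demo_config.yaml` for a complete configuration.

## Library example

```python
from chromolin import get_preset
from chromolin.simulate import simulate, apply_edu_pulse_chase
from chromolin import lineage, flipping, retention

sim = simulate(get_preset("dmatP"), layout="pad", n_lineages=100,
               duration=330, seed=1)
forest = lineage.build_forest(sim.cell_table)
traces, _ = flipping.build_traces(forest, sim.focus_table)
mean_flips, n_cycles = flipping.flips_per_cycle(traces)

pulsed = apply_edu_pulse_chase(sim, pulse_start=20, pulse_duration=15,
                               chase_duration=190)
calls, tally = retention.score_retention(pulsed.cell_table, pulsed.focus_table)
fraction, n = retention.retention_fraction(calls)
```

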