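"""Headline-statistic recomputation used by the acceptance report.

Each function simulates >= 3 seeded replicates of the relevant
phenomenological dataset, runs the corresponding pipeline stage from scratch,
and returns the replicate-averaged statistic on the percentage (or per-cycle)
scale, together with the pooled sample size and the per-replicate values.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from . import colocalization as coloc
from . import flipping as flip
from . import lineage as lin
from . import organization as org
from . import retention as ret
from .presets import get_preset
from .simulate import SimOutput, apply_edu_pulse_chase, simulate

N_REPLICATES = 3


def _seeds(seed: int) -> list[int]:
    return [seed * 1009 + 17 * i for i in range(N_REPLICATES)]


def _summary(per_rep: list[tuple[float, int]], scale: float = 100.0) -> dict:
    values = [v for v, _ in per_rep]
    ns = [n for _, n in per_rep]
    return {
        "value": float(np.mean(values)) * scale,
        "n": int(sum(ns)),
        "replicates": [float(v) * scale for v in values],
        "replicate_ns": ns,
    }


def dmukb_mother_machine_sims(seed: int, n_lineages: int = 115) -> list[SimOutput]:
    preset = get_preset("dmukB")
    return [
        simulate(preset, layout="mother_machine", n_lineages=n_lineages,
                 duration=1080.0, frame_interval=5.0, seed=s)
        for s in _seeds(seed)
    ]


def wt_pad_sims(seed: int, n_lineages: int = 200) -> list[SimOutput]:
    preset = get_preset("WT")
    return [
        simulate(preset, layout="pad", n_lineages=n_lineages, duration=480.0,
                 frame_interval=10.0, seed=s)
        for s in _seeds(seed)
    ]


def dmatp_pad_sims(seed: int, n_lineages: int = 200) -> list[SimOutput]:
    preset = get_preset("dmatP")
    return [
        simulate(preset, layout="pad", n_lineages=n_lineages, duration=480.0,
                 frame_interval=10.0, seed=s)
        for s in _seeds(seed)
    ]


def pulse_chase_sims(seed: int, strain: str = "WT", n_lineages: int = 170) -> list[SimOutput]:
    preset = get_preset(strain)
    if strain == "dmukB":
        # pulse-chase experiments were run in the slow-growth condition; the
        # anucleate machinery is irrelevant to retention scoring
        preset = preset.replace(
            generation_time_mean=150.0, generation_time_sd=10.0, p_anucleate=0.0
        )
    out = []
    for s in _seeds(seed):
        sim = simulate(preset, layout="pad", n_lineages=n_lineages, duration=400.0,
                       frame_interval=10.0, seed=s)
        out.append(apply_edu_pulse_chase(sim, pulse_start=20.0, pulse_duration=15.0,
                                         chase_duration=190.0))
    return out


# ---------------------------------------------------------------------------
# targets
# ---------------------------------------------------------------------------

def t1_t2_anucleate(sims: list[SimOutput]) -> tuple[dict, dict]:
    """t1: % divisions producing an anucleate daughter (deltaMukB).
    t2: % anucleate daughters at the mother's newer pole."""
    rates = []
    newpole = []
    for sim in sims:
        forest = lin.build_forest(sim.cell_table)
        records, _ = lin.detect_anucleate_divisions(forest, sim.focus_table)
        rates.append(lin.anucleate_rate(records))
        newpole.append(lin.anucleate_newpole_fraction(records))
    return _summary(rates), _summary(newpole)


def t3_opposite_halves(sims: list[SimOutput]) -> dict:
    """% single-focus-pair cells with L3 and R3 in opposite halves (WT)."""
    per_rep = []
    for sim in sims:
        oriented, _ = org.orient_cells(sim.focus_table, "L3_negative")
        frac, n, _ = org.opposite_halves_fraction(oriented)
        per_rep.append((frac, n))
    return _summary(per_rep)


def t4_translational(sims: list[SimOutput]) -> dict:
    """% of 2+2-focus cells classified TRANSLATIONAL (WT).

    Counted per cell (the configuration is a per-cycle property, so frames of
    one cycle are not independent observations): each cell contributes its
    last determinate call.
    """
    per_rep = []
    for sim in sims:
        oriented, _ = org.orient_cells(sim.focus_table, "L3_negative")
        calls, _ = org.classify_configuration(oriented)
        det = [c for c in calls if c.label != org.UNDETERMINED]
        last_by_cell: dict[int, str] = {}
        for c in sorted(det, key=lambda c: (c.cell_id, c.frame)):
            last_by_cell[c.cell_id] = c.label
        labels = list(last_by_cell.values())
        k = sum(lab == org.TRANSLATIONAL for lab in labels)
        per_rep.append((k / len(labels) if labels else float("nan"), len(labels)))
    return _summary(per_rep)


def t5_t6_mother_daughter_retention(sims: list[SimOutput]) -> dict:
    """% mother->daughter pairs retaining the arm-marker configuration."""
    per_rep = []
    for sim in sims:
        forest = lin.build_forest(sim.cell_table)
        traces, _ = flip.build_traces(forest, sim.focus_table)
        frac, n, _ = flip.mother_daughter_retention(forest, traces)
        per_rep.append((frac, n))
    return _summary(per_rep)


def t7_t8_flips_per_cycle(sims: list[SimOutput]) -> dict:
    """Mean pre-duplication orientation flips per cell cycle."""
    per_rep = []
    for sim in sims:
        forest = lin.build_forest(sim.cell_table)
        traces, _ = flip.build_traces(forest, sim.focus_table)
        per_rep.append(flip.flips_per_cycle(traces, flip.PRE_DUPLICATION))
    return _summary(per_rep, scale=1.0)


def t9_noncolocal(sims: list[SimOutput]) -> dict:
    """% DnaQ foci farther than 300 nm from the nearest DnaN focus (WT)."""
    per_rep = []
    for sim in sims:
        pairs = coloc.nearest_distances(sim.focus_table, "dnaQ", "dnaN")
        frac, n, _ = coloc.colocal_fraction(pairs, threshold=0.3)
        per_rep.append((1.0 - frac, n))
    return _summary(per_rep)


def t10_t11_strand_retention(sims: list[SimOutput]) -> dict:
    """% D-period cells with the EdU-free nucleoid nearer the Tsr-called
    older pole."""
    per_rep = []
    for sim in sims:
        calls, _ = ret.score_retention(sim.cell_table, sim.focus_table)
        per_rep.append(ret.retention_fraction(calls))
    return _summary(per_rep)


def t12_pole_call_accuracy(sims: list[SimOutput]) -> dict:
    """% cells whose Tsr-called older pole matches ground-truth pole age."""
    per_rep = []
    for sim in sims:
        calls, _ = ret.call_older_poles(sim.focus_table)
        truth = sim.truth_table.drop_duplicates("cell_id").set_index("cell_id")
        correct = []
        for c in calls:
            if c.older_pole is None or c.cell_id not in truth.index:
                continue
            row = truth.loc[c.cell_id]
            if row["pole_age_low"] == row["pole_age_high"]:
                continue
            true_old = "low" if row["pole_age_low"] > row["pole_age_high"] else "high"
            correct.append(c.older_pole == true_old)
        per_rep.append((float(np.mean(correct)), len(correct)))
    return _summary(per_rep)


#: paper-scale set points, for reference by callers (value, binomial flag)
SET_POINTS = {
    "t1": 15.7,
    "t2": 74.4,
    "t3": 97.8,
    "t4": 73.1,
    "t5": 91.4,
    "t6": 32.2,
    "t7": 0.78,
    "t8": 0.08,
    "t9": 41.2,
    "t10": 71.3,
    "t11": 48.5,
    "t12": 99.2,
}


def run_all_targets(seed: int, progress: Callable[[str], None] = lambda s: None) -> dict:
    """Recompute every acceptance target from scratch."""
    results: dict[str, dict] = {}

    progress("simulating deltaMukB mother-machine replicates (t1, t2)")
    mm = dmukb_mother_machine_sims(seed)
    results["t1"], results["t2"] = t1_t2_anucleate(mm)
    del mm

    progress("simulating WT pad replicates (t3, t4, t5, t8, t9)")
    wt = wt_pad_sims(seed + 1)
    results["t3"] = t3_opposite_halves(wt)
    results["t4"] = t4_translational(wt)
    results["t5"] = t5_t6_mother_daughter_retention(wt)
    results["t8"] = t7_t8_flips_per_cycle(wt)
    results["t9"] = t9_noncolocal(wt)
    del wt

    progress("simulating deltaMatP pad replicates (t6, t7)")
    mp = dmatp_pad_sims(seed + 2)
    results["t6"] = t5_t6_mother_daughter_retention(mp)
    results["t7"] = t7_t8_flips_per_cycle(mp)
    del mp

    progress("simulating WT pulse-chase replicates (t10, t12)")
    wtp = pulse_chase_sims(seed + 3, "WT")
    results["t10"] = t10_t11_strand_retention(wtp)
    results["t12"] = t12_pole_call_accuracy(wtp)
    del wtp

    progress("simulating deltaMukB pulse-chase replicates (t11)")
    mbp = pulse_chase_sims(seed + 4, "dmukB")
    results["t11"] = t10_t11_strand_retention(mbp)
    return results
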