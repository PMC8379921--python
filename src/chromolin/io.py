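"""Table schemas, config loading, pipeline orchestration, and run manifests.

The pipeline runs stages in dependency order (simulate -> lineage ->
organization / flipping / colocalization / retention) and writes per-stage
CSV/JSON outputs plus a manifest with content hashes so identical configs
reproduce identical outputs verifiably.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import shutil
import time
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .presets import PHENOMENOLOGICAL, get_preset, preset_from_dict
from .simulate import apply_edu_pulse_chase, simulate
from . import colocalization as coloc
from . import flipping as flip
from . import lineage as lin
from . import organization as org
from . import retention as ret

logger = logging.getLogger(__name__)

ALL_STAGES = ["lineage", "organization", "flipping", "colocalization", "retention"]

CELL_TABLE_REQUIRED = ["cell_id", "mother_id", "frame", "length_um", "low_end_um", "high_end_um"]
FOCUS_TABLE_REQUIRED = ["cell_id", "frame", "marker", "position_um", "intensity"]


class ConfigError(ValueError):
    pass


def validate_table(df: pd.DataFrame, required: list[str], context: str) -> None:
    """Check required columns; unknown columns are preserved, never dropped."""
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigError(f"{context}: missing required columns {missing}")


def load_config(path: str) -> dict[str, Any]:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


def _resolve_preset(cfg: dict[str, Any]):
    preset_spec = cfg.get("preset", "WT")
    mode = cfg.get("mode", PHENOMENOLOGICAL)
    if isinstance(preset_spec, str):
        preset = get_preset(preset_spec, mode)
    elif isinstance(preset_spec, dict):
        preset = preset_from_dict(preset_spec)
    else:
        raise ConfigError("preset must be a registered name or a mapping of fields")
    overrides = cfg.get("preset_overrides")
    if overrides:
        preset = preset.replace(**overrides)
    return preset


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_pipeline(config_path: str, outdir: Optional[str] = None) -> dict[str, Any]:
    """Execute the configured stages; returns the summary dictionary.

    Partial outputs are removed when a stage fails.
    """
    cfg = load_config(config_path)
    outdir = outdir or cfg.get("out", "chromolin_out")
    os.makedirs(outdir, exist_ok=True)
    try:
        return _run_pipeline_inner(cfg, config_path, outdir)
    except Exception:
        for name in os.listdir(outdir):
            p = os.path.join(outdir, name)
            if os.path.isfile(p):
                os.remove(p)
            else:
                shutil.rmtree(p)
        raise


def _run_pipeline_inner(cfg: dict, config_path: str, outdir: str) -> dict[str, Any]:
    t0 = time.time()
    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages", ALL_STAGES)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    frame_interval = cfg.get("frame_interval")
    summary: dict[str, Any] = {"seed": seed, "version": __version__}
    outputs: list[str] = []

    if "inputs" in cfg:
        paths = cfg["inputs"]
        for key in ("cell_table", "focus_table"):
            if key not in paths:
                raise ConfigError(f"analyze-only config must provide inputs.{key}")
        cell_table = pd.read_csv(paths["cell_table"])
        focus_table = pd.read_csv(paths["focus_table"])
        validate_table(cell_table, CELL_TABLE_REQUIRED, paths["cell_table"])
        validate_table(focus_table, FOCUS_TABLE_REQUIRED, paths["focus_table"])
        if frame_interval is None:
            raise ConfigError("analyze-only config must set frame_interval")
        sim = None
    else:
        preset = _resolve_preset(cfg)
        sim = simulate(
            preset,
            layout=cfg.get("layout", "pad"),
            n_lineages=int(cfg.get("n_lineages", 20)),
            duration=float(cfg.get("duration", 2.5 * preset.generation_time_mean)),
            frame_interval=frame_interval,
            seed=seed,
        )
        if "edu_pulse" in cfg:
            ep = cfg["edu_pulse"]
            sim = apply_edu_pulse_chase(
                sim, ep["pulse_start"], ep["pulse_duration"], ep["chase_duration"]
            )
        sim.save(outdir)
        outputs += ["cell_table.csv", "focus_table.csv", "truth_table.csv"]
        cell_table, focus_table = sim.cell_table, sim.focus_table
        frame_interval = sim.frame_interval
        summary["preset"] = preset.name
        summary["mode"] = preset.mode

    forest = lin.build_forest(cell_table)

    if "lineage" in stages:
        records, tally = lin.detect_anucleate_divisions(forest, focus_table)
        rate, n_div = lin.anucleate_rate(records)
        newpole, n_anuc = lin.anucleate_newpole_fraction(records)
        metrics, cycle_tally = lin.cycle_metrics(forest, frame_interval)
        pd.DataFrame(
            [
                {
                    "mother_id": r.mother_id,
                    "frame": r.frame,
                    "daughter_low": r.daughter_ids[0],
                    "daughter_high": r.daughter_ids[1],
                    "anucleate_daughter": r.anucleate_daughter,
                    "pole_side": r.pole_side,
                }
                for r in records
            ]
        ).to_csv(os.path.join(outdir, "division_records.csv"), index=False)
        metrics.to_csv(os.path.join(outdir, "cycle_metrics.csv"), index=False)
        outputs += ["division_records.csv", "cycle_metrics.csv"]
        summary["lineage"] = {
            "n_divisions": n_div,
            "anucleate_rate": rate,
            "anucleate_newpole_fraction": newpole,
            "n_anucleate_with_pole": n_anuc,
            "exclusions": tally,
            "cycles": cycle_tally,
            "generation_time_mean_min": (
                float(metrics["generation_time_min"].mean()) if len(metrics) else None
            ),
        }
        logger.info("lineage: %s", summary["lineage"])

    oriented, n_unoriented = org.orient_cells(focus_table)

    if "organization" in stages:
        frac, n, se = org.opposite_halves_fraction(oriented)
        distances, excl = org.arm_distance(focus_table)
        calls, cfg_tally = org.classify_configuration(oriented)
        tfrac, tn = org.translational_fraction(calls)
        arm_rows = focus_table[focus_table["marker"].isin(["L3", "R3"])]
        merged = arm_rows.merge(
            cell_table[["cell_id", "frame", "length_um"]], on=["cell_id", "frame"]
        )
        dg = org.demograph(
            merged["position_um"].to_numpy(), merged["length_um"].to_numpy()
        )
        np.savetxt(os.path.join(outdir, "demograph_L3R3.tsv"), dg.matrix, delimiter="\t")
        outputs.append("demograph_L3R3.tsv")
        summary["organization"] = {
            "opposite_halves_fraction": frac,
            "opposite_halves_n": n,
            "opposite_halves_se": se,
            "arm_distance_mean_um": float(distances.mean()) if len(distances) else None,
            "arm_distance_sd_um": float(distances.std()) if len(distances) else None,
            "translational_fraction": tfrac,
            "translational_n": tn,
            "configuration_tally": cfg_tally,
            "unoriented_cell_frames": n_unoriented,
        }
        logger.info("organization: %s", summary["organization"])

    if "flipping" in stages:
        traces, excluded = flip.build_traces(forest, focus_table)
        fpc, n_cycles = flip.flips_per_cycle(traces)
        retained, n_pairs, pair_excl = flip.mother_daughter_retention(forest, traces)
        stability, n_stab = flip.post_duplication_stability(traces)
        prof = flip.flip_probability_vs_length(traces)
        prof.to_csv(os.path.join(outdir, "flip_probability_vs_length.csv"), index=False)
        outputs.append("flip_probability_vs_length.csv")
        summary["flipping"] = {
            "flips_per_cycle_pre_duplication": fpc,
            "n_complete_cycles": n_cycles,
            "mother_daughter_retention": retained,
            "n_mother_daughter_pairs": n_pairs,
            "pairs_excluded": pair_excl,
            "post_duplication_stability": stability,
            "n_stability_cycles": n_stab,
            "traces_excluded": excluded,
        }
        logger.info("flipping: %s", summary["flipping"])

    if "colocalization" in stages:
        markers = set(focus_table["marker"].unique())
        if {"dnaQ", "dnaN"} <= markers:
            pairs = coloc.nearest_distances(focus_table, "dnaQ", "dnaN")
            frac, n, _ = coloc.colocal_fraction(pairs)
            pairs.table.to_csv(os.path.join(outdir, "dnaQ_dnaN_distances.csv"), index=False)
            outputs.append("dnaQ_dnaN_distances.csv")
            summary["colocalization"] = {
                "colocal_fraction": frac,
                "noncolocal_fraction": 1.0 - frac,
                "n_pairs": n,
                "censored": pairs.n_censored,
            }
            logger.info("colocalization: %s", summary["colocalization"])
        else:
            summary["colocalization"] = {"skipped": "dnaQ/dnaN not in focus table"}

    if "retention" in stages:
        edu_frames = focus_table.loc[focus_table["marker"] == "edu", "frame"]
        if len(edu_frames):
            snapshot = int(edu_frames.max())
            calls, tally = ret.score_retention(cell_table, focus_table)
            frac, n = ret.retention_fraction(calls)
            tests = ret.retention_tests(frac, n) if n else {}
            pd.DataFrame(
                [
                    {
                        "cell_id": c.cell_id,
                        "older_pole": c.older_pole,
                        "edu_nucleoid_pos": c.edu_nucleoid_pos,
                        "call": c.call,
                    }
                    for c in calls
                ]
            ).to_csv(os.path.join(outdir, "retention_calls.csv"), index=False)
            outputs.append("retention_calls.csv")
            summary["retention"] = {
                "snapshot_frame": snapshot,
                "retention_fraction": frac,
                "n_scored": n,
                "tally": tally,
                "tests": tests,
            }
            logger.info("retention: %s", summary["retention"])
        else:
            summary["retention"] = {"skipped": "no EdU channel in focus table"}

    summary_path = os.path.join(outdir, "summary.json")
    with open(summary_path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(summary), fh, indent=2)
    outputs.append("summary.json")

    manifest = {
        "config_sha256": _sha256(config_path),
        "seed": seed,
        "version": __version__,
        "elapsed_s": round(time.time() - t0, 2),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {
            name: _sha256(os.path.join(outdir, name))
            for name in outputs
            if os.path.exists(os.path.join(outdir, name))
        },
    }
    with open(os.path.join(outdir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return summary
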