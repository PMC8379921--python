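"""Ancestral-strand retention pipeline: Tsr-based older-pole calls, EdU
nucleoid scoring, retention fraction, and its statistical assessment."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .stats import binomial_two_tailed, two_proportion_z

ANCESTRAL_AT_OLD_POLE = "ANCESTRAL_AT_OLD_POLE"
ANCESTRAL_AT_NEW_POLE = "ANCESTRAL_AT_NEW_POLE"
UNDETERMINED = "UNDETERMINED"


@dataclass
class PoleCall:
    cell_id: int
    older_pole: Optional[str]  # 'low' | 'high' | None (UNDETERMINED)
    margin: float  # |I_a - I_b| / (I_a + I_b)


@dataclass
class RetentionCall:
    cell_id: int
    older_pole: Optional[str]
    edu_nucleoid_pos: Optional[float]
    nucleoid_count: int
    call: str


def call_older_pole(i_low: Optional[float], i_high: Optional[float]) -> tuple[Optional[str], float]:
    """Pick the pole with the greater polar intensity.

    Returns (pole, margin) where margin = |I_low - I_high| / (I_low + I_high).
    Exact ties or a missing intensity give (None, 0.0).
    """
    if i_low is None or i_high is None or np.isnan(i_low) or np.isnan(i_high):
        return None, 0.0
    if i_low == i_high:
        return None, 0.0
    margin = abs(i_low - i_high) / (i_low + i_high)
    return ("low" if i_low > i_high else "high"), float(margin)


def call_older_poles(
    focus_table: pd.DataFrame, frame: Optional[int] = None, marker: str = "tsr"
) -> tuple[list[PoleCall], int]:
    """Per-cell older-pole calls from polar marker intensities.

    Uses the two polar foci (most negative and most positive position) at the
    given frame (default: each cell's last frame with the marker).  Cells
    with a missing polar intensity are UNDETERMINED and tallied.
    """
    sub = focus_table[focus_table["marker"] == marker]
    if frame is not None:
        sub = sub[sub["frame"] == frame]
    calls: list[PoleCall] = []
    n_missing = 0
    for cid, grp in sub.groupby("cell_id"):
        last = grp[grp["frame"] == grp["frame"].max()].sort_values("position_um")
        if len(last) < 2:
            calls.append(PoleCall(int(cid), None, 0.0))
            n_missing += 1
            continue
        i_low = float(last["intensity"].iloc[0])
        i_high = float(last["intensity"].iloc[-1])
        pole, margin = call_older_pole(i_low, i_high)
        calls.append(PoleCall(int(cid), pole, margin))
        if pole is None:
            n_missing += 1
    return calls, n_missing


def score_retention(
    cell_table: pd.DataFrame,
    focus_table: pd.DataFrame,
    frame: Optional[int] = None,
    pole_calls: Optional[list[PoleCall]] = None,
) -> tuple[list[RetentionCall], dict[str, int]]:
    """Score ancestral-strand retention for D-period cells.

    With ``frame`` given, scores the snapshot at that frame; otherwise each
    cell is scored once, at its last frame carrying DAPI data (fixed-cell
    snapshot semantics without requiring population synchrony).

    A cell is scorable when it shows exactly two DAPI nucleoids with EdU foci
    confined to exactly one of them and a determinate older-pole call.  The
    call is ANCESTRAL_AT_OLD_POLE iff the EdU-free nucleoid is nearer the
    called older pole (nucleoid centroid vs pole position; equidistant ->
    UNDETERMINED).  Relabeling the two cell ends leaves every call unchanged.
    """
    dapi_all = focus_table[focus_table["marker"] == "dapi"]
    if frame is not None:
        score_frame = {int(c): frame for c in dapi_all.loc[dapi_all["frame"] == frame, "cell_id"].unique()}
    else:
        score_frame = dapi_all.groupby("cell_id")["frame"].max().astype(int).to_dict()
        score_frame = {int(c): f for c, f in score_frame.items()}

    cells = cell_table.set_index(["cell_id", "frame"])
    tsr = focus_table[focus_table["marker"] == "tsr"]
    if pole_calls is None:
        wanted = pd.DataFrame(
            {"cell_id": list(score_frame), "frame": list(score_frame.values())}
        )
        tsr_sel = tsr.merge(wanted, on=["cell_id", "frame"])
        pole_calls, _ = call_older_poles(tsr_sel)
    pole_by_cell = {c.cell_id: c for c in pole_calls}

    dapi = dapi_all.merge(
        pd.DataFrame({"cell_id": list(score_frame), "frame": list(score_frame.values())}),
        on=["cell_id", "frame"],
    )
    edu = focus_table[focus_table["marker"] == "edu"]
    edu_by_cf = dict(tuple(edu.groupby(["cell_id", "frame"])))

    calls: list[RetentionCall] = []
    tally = {
        "scored": 0,
        "not_two_nucleoids": 0,
        "edu_not_single_nucleoid": 0,
        "no_pole_call": 0,
        "equidistant": 0,
    }
    for cid, grp in dapi.groupby("cell_id"):
        cid = int(cid)
        nucleoids = np.sort(grp["position_um"].to_numpy(float))
        if len(nucleoids) != 2:
            tally["not_two_nucleoids"] += 1
            calls.append(RetentionCall(cid, None, None, len(nucleoids), UNDETERMINED))
            continue
        e = edu_by_cf.get((cid, score_frame[cid]))
        if e is None or e.empty:
            tally["edu_not_single_nucleoid"] += 1
            calls.append(RetentionCall(cid, None, None, 2, UNDETERMINED))
            continue
        # assign each EdU focus to its nearest nucleoid
        epos = e["position_um"].to_numpy(float)
        assigned = np.argmin(
            np.abs(epos[:, None] - nucleoids[None, :]), axis=1
        )
        labeled = set(assigned.tolist())
        if len(labeled) != 1:
            tally["edu_not_single_nucleoid"] += 1
            calls.append(RetentionCall(cid, None, None, 2, UNDETERMINED))
            continue
        labeled_idx = labeled.pop()
        free_pos = nucleoids[1 - labeled_idx]
        edu_pos = nucleoids[labeled_idx]
        pc = pole_by_cell.get(cid)
        if pc is None or pc.older_pole is None:
            tally["no_pole_call"] += 1
            calls.append(RetentionCall(cid, None, float(edu_pos), 2, UNDETERMINED))
            continue
        try:
            L = float(cells.loc[(cid, score_frame[cid]), "length_um"])
        except KeyError:
            tally["no_pole_call"] += 1
            continue
        pole_pos = -L / 2.0 if pc.older_pole == "low" else L / 2.0
        d_free = abs(free_pos - pole_pos)
        d_labeled = abs(edu_pos - pole_pos)
        if d_free == d_labeled:
            tally["equidistant"] += 1
            calls.append(RetentionCall(cid, pc.older_pole, float(edu_pos), 2, UNDETERMINED))
            continue
        call = ANCESTRAL_AT_OLD_POLE if d_free < d_labeled else ANCESTRAL_AT_NEW_POLE
        tally["scored"] += 1
        calls.append(RetentionCall(cid, pc.older_pole, float(edu_pos), 2, call))
    return calls, tally


def retention_fraction(calls: list[RetentionCall]) -> tuple[float, int]:
    """Fraction of determinate calls with the ancestral strand at the old
    pole.  Determinate calls partition exactly into the two outcomes."""
    det = [c for c in calls if c.call != UNDETERMINED]
    if not det:
        return float("nan"), 0
    k = sum(c.call == ANCESTRAL_AT_OLD_POLE for c in det)
    return k / len(det), len(det)


def retention_tests(
    fraction: float,
    n: int,
    per_replicate_fractions: Optional[list[float]] = None,
    per_replicate_ns: Optional[list[int]] = None,
    reference_fraction: Optional[float] = None,
    reference_n: Optional[int] = None,
) -> dict:
    """Statistical assessment of a retention fraction.

    Returns the two-tailed binomial test against 0.5, optionally the pooled
    two-proportion z-test against a reference strain, and the
    binomial-dispersion check: observed between-replicate SD vs the binomial
    SD sqrt(p(1-p)/n_bar) at the mean replicate size.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    k = int(round(fraction * n))
    out: dict = {"binomial_vs_half": binomial_two_tailed(k, n, 0.5).__dict__}
    if reference_fraction is not None and reference_n is not None:
        k_ref = int(round(reference_fraction * reference_n))
        out["z_vs_reference"] = two_proportion_z(k, n, k_ref, reference_n).__dict__
    if per_replicate_fractions:
        reps = np.asarray(per_replicate_fractions, float)
        observed_sd = float(np.std(reps, ddof=1)) if len(reps) > 1 else float("nan")
        if per_replicate_ns:
            n_bar = float(np.mean(per_replicate_ns))
        else:
            n_bar = n / len(reps)
        p = float(np.mean(reps))
        out["dispersion"] = {
            "observed_sd": observed_sd,
            "binomial_sd": float(np.sqrt(p * (1 - p) / n_bar)),
            "n_bar": n_bar,
            "n_replicates": len(reps),
        }
    return out
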