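"""Locus-position statistics: orientation normalization, demographs, arm
distance, opposite-half fraction, and sister-configuration classification."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TRANSLATIONAL = "TRANSLATIONAL"
MIRROR = "MIRROR"
UNDETERMINED = "UNDETERMINED"

_ORIENT_RULES = {"L3_negative": "L3", "ter3_negative": "ter3"}


def orient_cells(
    focus_table: pd.DataFrame, rule: str = "L3_negative"
) -> tuple[pd.DataFrame, int]:
    """Fix the per-cell-frame sign so the reference marker sits at <= 0.

    Returns a copy of the table with ``position_um`` sign-adjusted and an
    ``oriented`` flag, plus the number of cell-frames left unoriented because
    the reference marker was absent.  A reference marker exactly at 0 breaks
    the tie toward +1 (no flip).
    """
    if rule not in _ORIENT_RULES:
        raise ValueError(f"unknown orientation rule {rule!r}; use one of {list(_ORIENT_RULES)}")
    ref = _ORIENT_RULES[rule]
    out = focus_table.copy()
    ref_mean = (
        out[out["marker"] == ref]
        .groupby(["cell_id", "frame"])["position_um"]
        .mean()
        .rename("ref_pos")
    )
    keys = pd.MultiIndex.from_frame(out[["cell_id", "frame"]])
    ref_pos = ref_mean.reindex(keys).to_numpy()
    # sign +1 when ref <= 0 (tie toward +1), -1 when ref > 0
    sign = np.where(ref_pos > 0, -1.0, 1.0)
    oriented = ~np.isnan(ref_pos)
    out["position_um"] = np.where(oriented, out["position_um"] * sign, out["position_um"])
    out["oriented"] = oriented
    n_unoriented = int(
        out.loc[~out["oriented"], ["cell_id", "frame"]].drop_duplicates().shape[0]
    )
    return out, n_unoriented


@dataclass
class Demograph:
    """Counts over (signed position bin x cell-length bin), optionally
    per-length-column max-normalized."""

    matrix: np.ndarray  # shape (n_pos_bins, n_length_bins)
    pos_edges: np.ndarray
    length_edges: np.ndarray
    normalized: bool
    n_rejected: int = 0

    def normalize(self) -> "Demograph":
        """Divide each length column by its own max (idempotent; empty
        columns stay all-zero)."""
        m = self.matrix.astype(float).copy()
        col_max = m.max(axis=0)
        nonempty = col_max > 0
        m[:, nonempty] = m[:, nonempty] / col_max[nonempty]
        return Demograph(m, self.pos_edges, self.length_edges, True, self.n_rejected)


def demograph(
    positions: np.ndarray,
    lengths: np.ndarray,
    length_bin: float = 0.1,
    pos_bin: float = 0.05,
    normalize: bool = True,
) -> Demograph:
    """Histogram signed positions against cell length.

    Rows with a position outside [-L/2, L/2] are rejected and tallied.
    """
    if length_bin <= 0 or pos_bin <= 0:
        raise ValueError("bin widths must be > 0")
    positions = np.asarray(positions, float)
    lengths = np.asarray(lengths, float)
    ok = np.abs(positions) <= lengths / 2.0
    n_rejected = int((~ok).sum())
    positions, lengths = positions[ok], lengths[ok]
    if len(lengths) == 0:
        edges = np.array([0.0, length_bin])
        pedges = np.array([-pos_bin, pos_bin])
        return Demograph(np.zeros((1, 1)), pedges, edges, normalize, n_rejected)
    lmin, lmax = lengths.min(), lengths.max()
    ledges = np.arange(
        np.floor(lmin / length_bin) * length_bin,
        lmax + length_bin,
        length_bin,
    )
    pmax = (lengths.max() / 2.0) + pos_bin
    pedges = np.arange(-pmax, pmax + pos_bin, pos_bin)
    mat, pe, le = np.histogram2d(positions, lengths, bins=(pedges, ledges))
    dg = Demograph(mat, pe, le, False, n_rejected)
    return dg.normalize() if normalize else dg


def _single_pair_frames(focus_table: pd.DataFrame) -> pd.DataFrame:
    """Cell-frames with exactly one L3 and one R3 focus, as wide columns."""
    arms = focus_table[focus_table["marker"].isin(["L3", "R3"])]
    counts = arms.pivot_table(
        index=["cell_id", "frame"], columns="marker", values="position_um", aggfunc="count"
    ).fillna(0)
    if "L3" not in counts.columns or "R3" not in counts.columns:
        return pd.DataFrame(columns=["cell_id", "frame", "L3", "R3"])
    single = counts[(counts["L3"] == 1) & (counts["R3"] == 1)].index
    pos = arms.set_index(["cell_id", "frame"]).loc[
        arms.set_index(["cell_id", "frame"]).index.isin(single)
    ]
    wide = pos.pivot_table(
        index=["cell_id", "frame"], columns="marker", values="position_um"
    ).reset_index()
    return wide


def arm_distance(focus_table: pd.DataFrame) -> tuple[pd.Series, int]:
    """|pos(L3) - pos(R3)| per single-L3/single-R3 cell-frame.

    Multi-focus cell-frames are excluded; the exclusion count is returned.
    """
    arms = focus_table[focus_table["marker"].isin(["L3", "R3"])]
    total = arms[["cell_id", "frame"]].drop_duplicates().shape[0]
    wide = _single_pair_frames(focus_table)
    distances = (wide["L3"] - wide["R3"]).abs()
    distances.name = "arm_distance_um"
    return distances, total - len(wide)


def opposite_halves_fraction(
    focus_table: pd.DataFrame,
) -> tuple[float, int, float]:
    """Fraction of single-focus-pair cell-frames with L3 and R3 in opposite
    halves.  Returns (fraction, n, binomial SE).  Invariant under the
    orientation rule because the comparison is between the two markers.

    A focus exactly at 0 takes the half of the cell's nearest previous frame
    for that marker, else the negative half (deterministic tie rule)."""
    wide = _single_pair_frames(focus_table).sort_values(["cell_id", "frame"])
    if wide.empty:
        return float("nan"), 0, float("nan")
    cids = wide["cell_id"].to_numpy()
    sL = np.sign(wide["L3"].to_numpy(float))
    sR = np.sign(wide["R3"].to_numpy(float))
    if (sL == 0).any() or (sR == 0).any():
        histL: dict[int, float] = {}
        histR: dict[int, float] = {}
        for i, cid in enumerate(cids):
            cid = int(cid)
            if sL[i] == 0:
                sL[i] = histL.get(cid, -1.0)
            if sR[i] == 0:
                sR[i] = histR.get(cid, -1.0)
            histL[cid] = sL[i]
            histR[cid] = sR[i]
    opposite = sL != sR
    n = len(opposite)
    p = float(opposite.mean())
    se = float(np.sqrt(p * (1 - p) / n)) if n else float("nan")
    return p, n, se


@dataclass
class ConfigurationCall:
    cell_id: int
    frame: int
    label: str  # TRANSLATIONAL | MIRROR | UNDETERMINED
    sequence: str  # marker order by signed position, e.g. "LRLR"


def classify_configuration(
    focus_table: pd.DataFrame,
    position_resolution: float = 0.01,
) -> tuple[list[ConfigurationCall], dict[str, int]]:
    """Classify 2 L3 + 2 R3 cell-frames as TRANSLATIONAL (LRLR/RLRL) or
    MIRROR (LRRL/RLLR).

    Positions closer than ``position_resolution`` make the ordering
    ambiguous -> UNDETERMINED.  Cell-frames with any other multiplicity
    (including 3-focus merge artifacts) are tallied and skipped.
    The label is invariant under a global sign flip of all positions.
    """
    arms = focus_table[focus_table["marker"].isin(["L3", "R3"])]
    calls: list[ConfigurationCall] = []
    tally = {"classified": 0, "wrong_multiplicity": 0, "tied": 0}
    for (cid, frame), grp in arms.groupby(["cell_id", "frame"], sort=True):
        nL = int((grp["marker"] == "L3").sum())
        nR = int((grp["marker"] == "R3").sum())
        if nL != 2 or nR != 2:
            tally["wrong_multiplicity"] += 1
            continue
        g = grp.sort_values("position_um")
        pos = g["position_um"].to_numpy(float)
        seq = "".join("L" if m == "L3" else "R" for m in g["marker"])
        if np.any(np.diff(pos) < position_resolution):
            tally["tied"] += 1
            calls.append(ConfigurationCall(int(cid), int(frame), UNDETERMINED, seq))
            continue
        if seq in ("LRLR", "RLRL"):
            label = TRANSLATIONAL
        elif seq in ("LRRL", "RLLR"):
            label = MIRROR
        else:
            label = UNDETERMINED
        if label != UNDETERMINED:
            tally["classified"] += 1
        calls.append(ConfigurationCall(int(cid), int(frame), label, seq))
    return calls, tally


def translational_fraction(calls: list[ConfigurationCall]) -> tuple[float, int]:
    """Fraction of determinate calls labeled TRANSLATIONAL."""
    det = [c for c in calls if c.label != UNDETERMINED]
    if not det:
        return float("nan"), 0
    k = sum(c.label == TRANSLATIONAL for c in det)
    return k / len(det), len(det)
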