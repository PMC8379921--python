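"""Time-lapse orientation dynamics.

Builds per-cycle orientation traces from arm-marker foci (sign of
pos(R3) - pos(L3) while each marker shows a single focus), counts debounced
flip events before locus duplication, estimates the per-observation flip
hazard as a function of cell length, and measures mother-to-daughter
configuration retention and post-duplication stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .lineage import CellNode, LineageForest

PRE_DUPLICATION = "pre_duplication"
FULL = "full"


@dataclass
class FlipEvent:
    cell_id: int
    frame: int  # first frame showing the new sign
    length_um: float
    post_duplication: bool


@dataclass
class OrientationTrace:
    """Orientation observables for one cell cycle."""

    cell_id: int
    frames: np.ndarray
    signs: np.ndarray  # +1 / -1 / 0 (UNDEFINED)
    lengths: np.ndarray
    duplication_frame: Optional[int]
    flips: list[FlipEvent] = field(default_factory=list)
    config_signs: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    complete: bool = False  # birth and division both observed

    def flip_count(self, scope: str = PRE_DUPLICATION) -> int:
        if scope == PRE_DUPLICATION:
            return sum(not f.post_duplication for f in self.flips)
        return len(self.flips)

    def last_config_sign(self) -> int:
        """Configuration identity (+1 LRLR / -1 RLRL / 0) at the last frame."""
        if self.config_signs.size == 0:
            return 0
        return int(self.config_signs[-1])

    def first_defined_sign(self) -> int:
        nz = self.signs[self.signs != 0]
        return int(nz[0]) if nz.size else 0


def _frame_features(arms: pd.DataFrame) -> pd.DataFrame:
    """Per (cell_id, frame): L3/R3 focus counts, the single-focus orientation
    sign, and the four-focus configuration identity sign."""
    if arms.empty:
        return pd.DataFrame(
            columns=["cell_id", "frame", "nL", "nR", "sign", "config_sign"]
        )
    agg = arms.pivot_table(
        index=["cell_id", "frame"],
        columns="marker",
        values="position_um",
        aggfunc=["count", "mean", "min", "max"],
    )

    def col(stat: str, marker: str, default: float) -> np.ndarray:
        if (stat, marker) in agg.columns:
            return agg[(stat, marker)].to_numpy(float)
        return np.full(len(agg), default)

    nL = np.nan_to_num(col("count", "L3", 0.0)).astype(int)
    nR = np.nan_to_num(col("count", "R3", 0.0)).astype(int)
    mL = col("mean", "L3", np.nan)
    mR = col("mean", "R3", np.nan)
    lmin, lmax = col("min", "L3", np.nan), col("max", "L3", np.nan)
    rmin, rmax = col("min", "R3", np.nan), col("max", "R3", np.nan)

    sign = np.zeros(len(agg), int)
    single = (nL == 1) & (nR == 1)
    with np.errstate(invalid="ignore"):
        sign[single] = np.sign(mR[single] - mL[single]).astype(int)

    config = np.zeros(len(agg), int)
    quad = (nL == 2) & (nR == 2)
    with np.errstate(invalid="ignore"):
        lrlr = quad & (lmin < rmin) & (rmin < lmax) & (lmax < rmax)
        rlrl = quad & (rmin < lmin) & (lmin < rmax) & (rmax < lmax)
    config[lrlr] = 1
    config[rlrl] = -1

    out = pd.DataFrame(
        {
            "nL": nL,
            "nR": nR,
            "sign": sign,
            "config_sign": config,
        },
        index=agg.index,
    ).reset_index()
    return out


def _detect_flips(
    cell: CellNode,
    signs: np.ndarray,
    dup_frame: Optional[int],
    persistence: int,
    max_gap: int,
) -> list[FlipEvent]:
    """Debounced flip detection: a candidate new sign is accepted only when
    it persists for >= ``persistence`` defined frames; transient excursions
    never change the accepted state.  UNDEFINED gaps longer than ``max_gap``
    censor the interval (state updates without an event)."""
    frames = cell.frames
    flips: list[FlipEvent] = []
    defined = np.nonzero(signs != 0)[0]
    state = 0
    prev_idx: Optional[int] = None
    for j, i1 in enumerate(defined):
        s = int(signs[i1])
        if state == 0:
            state = s
            prev_idx = i1
            continue
        if s == state:
            prev_idx = i1
            continue
        window = defined[j : j + persistence]
        if len(window) < persistence or any(signs[k] != s for k in window):
            continue  # transient
        gap = i1 - prev_idx - 1 if prev_idx is not None else 0
        if gap <= max_gap:
            flips.append(
                FlipEvent(
                    cell_id=cell.cell_id,
                    frame=int(frames[i1]),
                    length_um=float(cell.lengths[i1]),
                    post_duplication=dup_frame is not None and frames[i1] >= dup_frame,
                )
            )
        state = s
        prev_idx = i1
    return flips


def _trace_from_arrays(
    cell: CellNode,
    nL: np.ndarray,
    nR: np.ndarray,
    sign: np.ndarray,
    config_sign: np.ndarray,
    persistence: int,
    max_gap: int,
    coverage: float,
) -> Optional[OrientationTrace]:
    if (nL > 0).mean() < coverage or (nR > 0).mean() < coverage:
        return None
    frames = cell.frames
    # duplication frame: first frame where both markers persistently show >= 2
    both2 = (nL >= 2) & (nR >= 2)
    dup_idx: Optional[int] = None
    for i in range(len(frames)):
        if both2[i] and (i == len(frames) - 1 or both2[i + 1]):
            dup_idx = i
            break
    dup_frame = int(frames[dup_idx]) if dup_idx is not None else None

    signs = sign.copy()
    if dup_idx is not None:
        signs[dup_idx:] = 0

    flips = _detect_flips(cell, signs, dup_frame, persistence, max_gap)

    config_signs = np.zeros(len(frames), int)
    if dup_idx is not None:
        config_signs[dup_idx:] = config_sign[dup_idx:]

    return OrientationTrace(
        cell_id=cell.cell_id,
        frames=frames,
        signs=signs,
        lengths=cell.lengths,
        duplication_frame=dup_frame,
        flips=flips,
        config_signs=config_signs,
    )


def _align(features: pd.DataFrame, frames: np.ndarray) -> tuple[np.ndarray, ...]:
    """Align per-frame feature rows to a cell's frame vector (missing -> 0)."""
    n = len(frames)
    nL = np.zeros(n, int)
    nR = np.zeros(n, int)
    sign = np.zeros(n, int)
    config = np.zeros(n, int)
    if len(features):
        idx = {int(f): i for i, f in enumerate(frames)}
        for f, a, b, s, c in zip(
            features["frame"], features["nL"], features["nR"],
            features["sign"], features["config_sign"],
        ):
            i = idx.get(int(f))
            if i is not None:
                nL[i], nR[i], sign[i], config[i] = a, b, s, c
    return nL, nR, sign, config


def orientation_trace(
    cell: CellNode,
    focus_table: pd.DataFrame,
    persistence: int = 2,
    max_gap: int = 2,
    coverage: float = 0.5,
) -> Optional[OrientationTrace]:
    """Build the orientation trace for one cell cycle.

    Returns ``None`` (caller tallies the exclusion) when either arm marker is
    observed in fewer than ``coverage`` of the cell's frames.
    """
    arms = focus_table[
        (focus_table["cell_id"] == cell.cell_id)
        & (focus_table["marker"].isin(["L3", "R3"]))
    ]
    feats = _frame_features(arms)
    nL, nR, sign, config = _align(feats, cell.frames)
    return _trace_from_arrays(cell, nL, nR, sign, config, persistence, max_gap, coverage)


def build_traces(
    forest: LineageForest,
    focus_table: pd.DataFrame,
    persistence: int = 2,
    max_gap: int = 2,
) -> tuple[dict[int, OrientationTrace], int]:
    """Orientation traces for every cell in the forest; returns the traces
    keyed by cell id plus the count of excluded (under-covered) cells."""
    arms = focus_table[focus_table["marker"].isin(["L3", "R3"])]
    feats = _frame_features(arms)
    by_cell = dict(tuple(feats.groupby("cell_id"))) if len(feats) else {}
    empty = feats.iloc[0:0]
    traces: dict[int, OrientationTrace] = {}
    excluded = 0
    for cid, node in forest.nodes.items():
        sub = by_cell.get(cid, empty)
        nL, nR, sign, config = _align(sub, node.frames)
        tr = _trace_from_arrays(node, nL, nR, sign, config, persistence, max_gap, 0.5)
        if tr is None:
            excluded += 1
            continue
        tr.complete = node.mother_id in forest.nodes and len(node.daughters) == 2
        traces[cid] = tr
    return traces, excluded


def flips_per_cycle(
    traces: dict[int, OrientationTrace] | list[OrientationTrace],
    scope: str = PRE_DUPLICATION,
) -> tuple[float, int]:
    """Mean flip count over complete cycles within the given scope."""
    if scope not in (PRE_DUPLICATION, FULL):
        raise ValueError(f"scope must be {PRE_DUPLICATION!r} or {FULL!r}")
    vals = [
        t.flip_count(scope)
        for t in (traces.values() if isinstance(traces, dict) else traces)
        if t.complete
    ]
    if not vals:
        return float("nan"), 0
    return float(np.mean(vals)), len(vals)


def flip_probability_vs_length(
    traces: dict[int, OrientationTrace] | list[OrientationTrace],
    length_bin: float = 0.25,
) -> pd.DataFrame:
    """Per-length-bin flip probability: events / defined cell-frames.

    This is a per-observation hazard estimate; empty bins are reported with
    NaN probability, not zero.
    """
    if length_bin <= 0:
        raise ValueError("length_bin must be > 0")
    tlist = list(traces.values() if isinstance(traces, dict) else traces)
    frame_lengths = []
    event_lengths = []
    for t in tlist:
        pre = (
            t.frames < t.duplication_frame
            if t.duplication_frame is not None
            else np.ones(len(t.frames), bool)
        )
        defined = np.nonzero((t.signs != 0) & pre)[0]
        # a flip is only observable at frames with a preceding defined frame,
        # so the first defined frame of a trace is not an eligible observation
        frame_lengths.append(t.lengths[defined[1:]])
        event_lengths.extend(f.length_um for f in t.flips if not f.post_duplication)
    frame_lengths = (
        np.concatenate(frame_lengths) if frame_lengths else np.array([])
    )
    event_lengths = np.array(event_lengths)
    if frame_lengths.size == 0:
        return pd.DataFrame(columns=["length_mid", "n_frames", "n_flips", "probability"])
    lo = np.floor(frame_lengths.min() / length_bin) * length_bin
    edges = np.arange(lo, frame_lengths.max() + length_bin, length_bin)
    n_frames, _ = np.histogram(frame_lengths, bins=edges)
    n_flips, _ = np.histogram(event_lengths, bins=edges)
    prob = np.where(n_frames > 0, n_flips / np.maximum(n_frames, 1), np.nan)
    return pd.DataFrame(
        {
            "length_mid": (edges[:-1] + edges[1:]) / 2.0,
            "n_frames": n_frames,
            "n_flips": n_flips,
            "probability": prob,
        }
    )


def _daughter_axis_sign(mother: CellNode, daughter: CellNode) -> int:
    """+1 when the daughter's coordinate axis points the same way as the
    mother's (shared-pole mapping via end coordinates at birth)."""
    return 1 if daughter.high_ends[0] >= daughter.low_ends[0] else -1


def mother_daughter_retention(
    forest: LineageForest,
    traces: dict[int, OrientationTrace],
) -> tuple[float, int, int]:
    """Fraction of daughters whose first determinate orientation matches the
    mother's final pre-division configuration identity (LRLR vs RLRL), with
    the daughter compared in the mother's spatial frame.

    Pairs with an undetermined mother configuration (mirror or tied) or an
    undefined daughter orientation are excluded and tallied.
    Returns (fraction, n_pairs, n_excluded).
    """
    matched = 0
    n = 0
    excluded = 0
    for mother, d_low, d_high in forest.divisions():
        mtr = traces.get(mother.cell_id)
        if mtr is None or mtr.last_config_sign() == 0:
            excluded += 2
            continue
        m_sign = mtr.last_config_sign()
        for d in (d_low, d_high):
            dtr = traces.get(d.cell_id)
            d_sign = dtr.first_defined_sign() if dtr is not None else 0
            if d_sign == 0:
                excluded += 1
                continue
            d_sign *= _daughter_axis_sign(mother, d)
            n += 1
            matched += d_sign == m_sign
    if n == 0:
        return float("nan"), 0, excluded
    return matched / n, n, excluded


def post_duplication_stability(
    traces: dict[int, OrientationTrace] | list[OrientationTrace],
) -> tuple[float, int]:
    """Fraction of complete cycles whose configuration identity never changes
    between locus duplication and division."""
    tlist = [
        t
        for t in (traces.values() if isinstance(traces, dict) else traces)
        if t.complete and t.duplication_frame is not None
    ]
    n = 0
    stable = 0
    for t in tlist:
        post = t.config_signs[t.frames >= t.duplication_frame]
        post = post[post != 0]
        if post.size == 0:
            continue
        n += 1
        stable += bool(np.all(post == post[0]))
    if n == 0:
        return float("nan"), 0
    return stable / n, n
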