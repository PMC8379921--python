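"""Division-forest construction, pole-age propagation, and division analyses.

The input is a tidy tracked-cell table (one row per cell per frame).  The
forest links mothers to daughters, propagates pole identities (at every
division two age-0 poles are created at the septum; each daughter's distal
pole inherits the mother's corresponding pole, one generation older), and
supports anucleate-division detection, pre-division focus counting, and
per-cycle growth metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .presets import FROS_MARKERS

logger = logging.getLogger(__name__)

UNKNOWN = None


class SchemaError(ValueError):
    """Raised when a table violates the expected schema or link structure."""


@dataclass
class CellNode:
    """One tracked cell: its frames, geometry, links, and pole annotations."""

    cell_id: int
    mother_id: int
    channel: int
    frames: np.ndarray
    lengths: np.ndarray
    low_ends: np.ndarray
    high_ends: np.ndarray
    daughters: list[int] = field(default_factory=list)
    # pole annotations; ages in generations, None = UNKNOWN
    pole_age_low: Optional[int] = UNKNOWN
    pole_age_high: Optional[int] = UNKNOWN
    new_pole_end: Optional[str] = UNKNOWN  # 'low' | 'high'
    old_pole_end: Optional[str] = UNKNOWN

    @property
    def birth_frame(self) -> int:
        return int(self.frames[0])

    @property
    def last_frame(self) -> int:
        return int(self.frames[-1])

    @property
    def birth_length(self) -> float:
        return float(self.lengths[0])

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def length_at(self, frame: int) -> float:
        idx = np.searchsorted(self.frames, frame)
        if idx >= len(self.frames) or self.frames[idx] != frame:
            raise KeyError(f"cell {self.cell_id} not observed at frame {frame}")
        return float(self.lengths[idx])

    def center_at_last(self) -> float:
        return float((self.low_ends[-1] + self.high_ends[-1]) / 2.0)


@dataclass
class DivisionRecord:
    """One observed division, with optional anucleate-daughter attribution."""

    mother_id: int
    daughter_ids: tuple[int, int]
    frame: int
    daughter_birth_lengths: tuple[float, float]
    anucleate_daughter: Optional[int] = None
    pole_side: Optional[str] = None  # 'old' | 'new' | None (UNKNOWN)

    @property
    def is_anucleate(self) -> bool:
        return self.anucleate_daughter is not None


class LineageForest:
    """The division forest over tracked cells."""

    def __init__(self, nodes: dict[int, CellNode]):
        self.nodes = nodes
        self.roots = [n.cell_id for n in nodes.values() if n.mother_id not in nodes]

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, cell_id: int) -> bool:
        return cell_id in self.nodes

    def __getitem__(self, cell_id: int) -> CellNode:
        return self.nodes[cell_id]

    def divisions(self) -> list[tuple[CellNode, CellNode, CellNode]]:
        """(mother, low daughter, high daughter) for every observed division."""
        out = []
        for node in self.nodes.values():
            if len(node.daughters) == 2:
                d1, d2 = (self.nodes[d] for d in node.daughters)
                if d1.low_ends[0] > d2.low_ends[0]:
                    d1, d2 = d2, d1
                out.append((node, d1, d2))
        return out


def build_forest(cell_table: pd.DataFrame) -> LineageForest:
    """Build a :class:`LineageForest` from a tracked-cell table.

    Cells present in the first frame (or whose mother is not in the table)
    keep UNKNOWN pole ages; their descendants acquire a known *new* pole at
    the first observed division even when the inherited pole's age is
    unknown.
    """
    required = {"cell_id", "mother_id", "frame", "length_um", "low_end_um", "high_end_um"}
    missing = required - set(cell_table.columns)
    if missing:
        raise SchemaError(f"cell_table missing columns: {sorted(missing)}")
    if cell_table.empty:
        logger.warning("build_forest: empty cell table; returning empty forest")
        return LineageForest({})

    nodes: dict[int, CellNode] = {}
    has_channel = "channel_id" in cell_table.columns
    for cell_id, grp in cell_table.sort_values("frame").groupby("cell_id", sort=True):
        nodes[int(cell_id)] = CellNode(
            cell_id=int(cell_id),
            mother_id=int(grp["mother_id"].iloc[0]),
            channel=int(grp["channel_id"].iloc[0]) if has_channel else 0,
            frames=grp["frame"].to_numpy(int),
            lengths=grp["length_um"].to_numpy(float),
            low_ends=grp["low_end_um"].to_numpy(float),
            high_ends=grp["high_end_um"].to_numpy(float),
        )

    for node in nodes.values():
        if node.mother_id in nodes:
            mother = nodes[node.mother_id]
            if node.birth_frame <= mother.last_frame:
                raise SchemaError(
                    f"daughter {node.cell_id} born at frame {node.birth_frame} "
                    f"before mother {mother.cell_id} divided (last frame "
                    f"{mother.last_frame})"
                )
            mother.daughters.append(node.cell_id)

    for node in nodes.values():
        if len(node.daughters) > 2:
            raise SchemaError(
                f"cell {node.cell_id} has {len(node.daughters)} daughters: "
                f"{sorted(node.daughters)}"
            )

    # pole propagation, breadth-first from the roots
    forest = LineageForest(nodes)
    for mother, d_low, d_high in sorted(
        forest.divisions(), key=lambda t: (t[0].birth_frame, t[0].cell_id)
    ):
        # the septum is interior to the mother: each daughter's end nearer the
        # mother centre is its new pole
        d_low.new_pole_end = "high"
        d_low.old_pole_end = "low"
        d_high.new_pole_end = "low"
        d_high.old_pole_end = "high"
        d_low.pole_age_high = 0
        d_high.pole_age_low = 0
        d_low.pole_age_low = (
            mother.pole_age_low + 1 if mother.pole_age_low is not None else UNKNOWN
        )
        d_high.pole_age_high = (
            mother.pole_age_high + 1 if mother.pole_age_high is not None else UNKNOWN
        )
        # a mother with an observed division has a defined new pole; if she was
        # a root her own pole ends become known only through her daughters, so
        # nothing further propagates here
    return forest


def _fros_cells(focus_table: pd.DataFrame, markers=FROS_MARKERS) -> set[int]:
    mask = focus_table["marker"].isin(markers)
    return set(focus_table.loc[mask, "cell_id"].unique())


def detect_anucleate_divisions(
    forest: LineageForest,
    focus_table: pd.DataFrame,
    min_observation: int = 3,
    growth_threshold: float = 0.02,
) -> tuple[list[DivisionRecord], dict[str, int]]:
    """Flag divisions producing an anucleate daughter.

    A daughter is called anucleate when it shows no focus in any FROS channel
    over its observation window *and* its relative length change stays below
    ``growth_threshold``.  Divisions whose daughters are observed for fewer
    than ``min_observation`` frames are excluded (tallied, not guessed).

    Returns the records of all eligible divisions plus an exclusion tally.
    """
    fros = _fros_cells(focus_table)
    records: list[DivisionRecord] = []
    tally = {"eligible": 0, "too_brief": 0, "double_flagged": 0}

    def _is_anucleate(d: CellNode) -> bool:
        if d.cell_id in fros:
            return False
        growth = abs(d.lengths[-1] - d.lengths[0]) / d.lengths[0]
        return growth < growth_threshold

    for mother, d_low, d_high in forest.divisions():
        if min(d_low.n_frames, d_high.n_frames) < min_observation:
            tally["too_brief"] += 1
            continue
        flags = (_is_anucleate(d_low), _is_anucleate(d_high))
        if all(flags):
            tally["double_flagged"] += 1
            continue
        tally["eligible"] += 1
        anuc_daughter = None
        pole_side = None
        if any(flags):
            anuc = d_low if flags[0] else d_high
            anuc_daughter = anuc.cell_id
            # which mother pole does the anucleate daughter abut?
            mother_end = "low" if anuc is d_low else "high"
            if mother.old_pole_end is not None:
                pole_side = "old" if mother.old_pole_end == mother_end else "new"
        records.append(
            DivisionRecord(
                mother_id=mother.cell_id,
                daughter_ids=(d_low.cell_id, d_high.cell_id),
                frame=d_low.birth_frame,
                daughter_birth_lengths=(d_low.birth_length, d_high.birth_length),
                anucleate_daughter=anuc_daughter,
                pole_side=pole_side,
            )
        )
    return records, tally


def anucleate_rate(records: list[DivisionRecord]) -> tuple[float, int]:
    """Fraction of eligible divisions producing an anucleate daughter."""
    n = len(records)
    if n == 0:
        return float("nan"), 0
    k = sum(r.is_anucleate for r in records)
    return k / n, n


def anucleate_newpole_fraction(records: list[DivisionRecord]) -> tuple[float, int]:
    """Among anucleate divisions with known mother pole, fraction at the new pole."""
    sides = [r.pole_side for r in records if r.is_anucleate and r.pole_side is not None]
    if not sides:
        return float("nan"), 0
    return sides.count("new") / len(sides), len(sides)


def count_ori_foci_prior_division(
    forest: LineageForest,
    focus_table: pd.DataFrame,
    marker: str = "ori1",
    window: int = 1,
    merge_radius: float = 0.0,
) -> pd.DataFrame:
    """Focus count of ``marker`` in the mother's last frame(s) before division.

    Looks back up to ``window`` frames from the division for the most recent
    frame with at least one focus.  With ``merge_radius`` > 0, foci closer
    than the radius are counted as one (merge-aware counting on top of
    whatever merging the imaging already applied).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if marker not in set(focus_table["marker"].unique()):
        raise SchemaError(f"marker {marker!r} absent from focus table")
    sub = focus_table[focus_table["marker"] == marker]
    by_cell_frame = sub.groupby(["cell_id", "frame"])["position_um"].apply(list)

    rows = []
    for mother, d_low, _ in forest.divisions():
        count = 0
        for back in range(window):
            frame = mother.last_frame - back
            try:
                positions = by_cell_frame.loc[(mother.cell_id, frame)]
            except KeyError:
                continue
            positions = sorted(positions)
            if merge_radius > 0:
                merged = 1
                for a, b in zip(positions, positions[1:]):
                    if b - a >= merge_radius:
                        merged += 1
                count = merged
            else:
                count = len(positions)
            break
        rows.append((mother.cell_id, d_low.birth_frame, count))
    return pd.DataFrame(rows, columns=["mother_id", "division_frame", "focus_count"])


def cycle_metrics(
    forest: LineageForest, frame_interval: float = 5.0
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-cell generation time and division geometry for complete cycles.

    A cycle is complete when both the birth (mother observed) and the
    division (two daughters observed) are in the table; censored cells are
    excluded and tallied.
    """
    rows = []
    tally = {"complete": 0, "censored": 0}
    for node in forest.nodes.values():
        observed_birth = node.mother_id in forest.nodes
        if not observed_birth or len(node.daughters) != 2:
            tally["censored"] += 1
            continue
        tally["complete"] += 1
        d1, d2 = (forest[d] for d in node.daughters)
        division_frame = d1.birth_frame
        lengths = sorted((d1.birth_length, d2.birth_length))
        rows.append(
            (
                node.cell_id,
                (division_frame - node.birth_frame) * frame_interval,
                node.birth_length,
                float(node.lengths[-1]),
                lengths[0],
                lengths[1],
                lengths[1] - lengths[0],
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "generation_time_min",
            "birth_length_um",
            "division_length_um",
            "daughter_length_min_um",
            "daughter_length_max_um",
            "division_asymmetry_um",
        ],
    )
    return df, tally
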