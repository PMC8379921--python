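"""Seeded synthetic time-lapse generator.

Produces tracked-cell, focus, and ground-truth tables with the statistical
structure the analysis pipeline assumes, for a mother-machine or agarose-pad
layout.  Two modes:

* ``mechanistic`` — orientation flips follow a length-dependent hazard, sister
  chromosomes segregate translationally or mirror-wise, and strand-level
  semiconservative bookkeeping lets ancestral-strand retention *emerge*.
* ``phenomenological`` — each observable (opposite halves, configuration,
  flips per cycle, colocalization, retention, pole-call accuracy) is governed
  by a direct probability parameter, so the pipeline can be validated by
  parameter recovery.

Conventions: positions are signed along the long axis, origin at the cell
mid-point, in micrometres; the "low" end of a cell is the end with the
smaller global coordinate.  Frames are 0-based; minutes = frame *
frame_interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .presets import MECHANISTIC, StrainPreset

MOTHER_MACHINE = "mother_machine"
PAD = "pad"

#: default frame intervals per layout (minutes)
DEFAULT_FRAME_INTERVAL = {MOTHER_MACHINE: 5.0, PAD: 10.0}

#: frames a washed-out daughter stays in view in the mother machine
DAUGHTER_WINDOW = 6

CELL_COLUMNS = [
    "cell_id",
    "mother_id",
    "frame",
    "length_um",
    "channel_id",
    "low_end_um",
    "high_end_um",
]
FOCUS_COLUMNS = ["cell_id", "frame", "marker", "position_um", "intensity"]
TRUTH_COLUMNS = [
    "cell_id",
    "frame",
    "phase",
    "orientation",
    "config",
    "flip",
    "pole_age_low",
    "pole_age_high",
    "anucleate",
    "binucleate",
    "ancestral_side",
    "edu_side",
]


class SimulationError(ValueError):
    """Raised for invalid simulation arguments."""


@dataclass
class StrandRecord:
    """One DNA strand: age in generations and its synthesis interval."""

    age: int
    synth_start: float  # minutes (absolute); -inf for founder strands
    synth_end: float
    edu_labeled: bool = False


@dataclass
class ChromosomeState:
    """Ordered strand pair plus orientation bookkeeping (mechanistic mode)."""

    strand_template: StrandRecord  # older strand (templated this chromosome)
    strand_nascent: StrandRecord
    orientation: int  # +1: R3 toward the high end
    template_toward: int  # cell half (+1 high, -1 low) the template strand faces

    @property
    def strands(self) -> tuple[StrandRecord, StrandRecord]:
        return (self.strand_template, self.strand_nascent)

    @property
    def max_age(self) -> int:
        return max(self.strand_template.age, self.strand_nascent.age)


@dataclass
class _Cell:
    cell_id: int
    mother_id: int
    channel: int
    birth_frame: int  # may be negative for staggered founders
    div_frame: int  # exclusive; daughters born at this frame
    tracked_until: int  # exclusive
    birth_length: float
    low0: float
    high0: float
    pole_age_low: int
    pole_age_high: int
    new_pole_end: Optional[str]  # 'low' | 'high' | None for founders
    gen_time: float
    anucleate: bool = False
    binucleate: bool = False
    will_divide: bool = False
    will_anucleate: bool = False
    anucleate_side: Optional[int] = None  # +1 high / -1 low half of this cell
    # per-cycle draws
    dup_rel: int = 0  # cycle frame of arm-locus duplication
    ori_dup_rel: int = 0
    sign0: int = 1
    flip_rels: tuple[int, ...] = ()
    translational: bool = True
    postdup_change_rel: Optional[int] = None
    ori_separated: bool = True
    tsr_correct: bool = True
    tsr_margin: float = 30.0
    ancestral_side: int = 0  # +1/-1: half holding the older-template chromosome
    edu_state: str = "none"  # none | full | single
    chromosome: Optional[ChromosomeState] = None
    passenger: Optional[ChromosomeState] = None  # unreplicated extra chromosome
    daughters: tuple[ChromosomeState, ...] = ()
    daughter_sides: tuple[int, ...] = ()  # half of each daughter chromosome
    rng: np.random.Generator = field(default=None, repr=False)  # type: ignore

    # -- geometry -----------------------------------------------------------
    def n_cycle_frames(self) -> int:
        return self.div_frame - self.birth_frame

    def length_at(self, frame: int) -> float:
        if self.anucleate:
            return self.birth_length
        tau = (frame - self.birth_frame) / self.n_cycle_frames()
        return self.birth_length * 2.0 ** tau

    def tau_at(self, frame: int) -> float:
        if self.anucleate:
            return 0.0
        return (frame - self.birth_frame) / self.n_cycle_frames()

    def sign_at(self, rel: int) -> int:
        s = self.sign0
        for fr in self.flip_rels:
            if fr <= rel:
                s = -s
        return s

    def old_pole_side(self) -> int:
        """+1 if the high end is the older pole, -1 otherwise."""
        return 1 if self.pole_age_high >= self.pole_age_low else -1


@dataclass
class SimOutput:
    """Complete simulator output: observation tables plus ground truth."""

    cell_table: pd.DataFrame
    focus_table: pd.DataFrame
    truth_table: pd.DataFrame
    preset: StrainPreset
    layout: str
    frame_interval: float
    duration: float
    seed: int
    n_frames: int
    cells: list = field(default_factory=list, repr=False)

    def save(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.cell_table.to_csv(os.path.join(outdir, "cell_table.csv"), index=False)
        self.focus_table.to_csv(os.path.join(outdir, "focus_table.csv"), index=False)
        self.truth_table.to_csv(os.path.join(outdir, "truth_table.csv"), index=False)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def expected_flips_per_cycle(
    preset: StrainPreset,
    birth_length: Optional[float] = None,
    gen_time: Optional[float] = None,
) -> float:
    """Analytic expected flip count over the pre-duplication window.

    Integrates ``hazard(l(t)) = base + slope * l(t)`` with exponential growth
    ``l(t) = l0 * 2**(t/T)`` from 0 to ``arm_dup_frac * T``.
    """
    if preset.mode != MECHANISTIC:
        raise SimulationError("expected_flips_per_cycle applies to mechanistic presets")
    l0 = birth_length if birth_length is not None else preset.birth_length_mean
    T = gen_time if gen_time is not None else preset.generation_time_mean
    tau = preset.arm_dup_frac * T
    base = preset.flip_hazard_base
    slope = preset.flip_hazard_length_slope
    integral_l = l0 * T / math.log(2.0) * (2.0 ** (tau / T) - 1.0)
    return base * tau + slope * integral_l


def expected_flips_discrete(
    preset: StrainPreset,
    birth_length: float,
    n_cycle_frames: int,
    dup_rel: int,
    frame_interval: float,
) -> float:
    """Expected flip count under the per-frame Bernoulli discretization
    actually used by the simulator: sum of min(1, hazard(l) * dt) over the
    pre-duplication frames of one cycle."""
    if preset.mode != MECHANISTIC:
        raise SimulationError("expected_flips_discrete applies to mechanistic presets")
    total = 0.0
    for rel in range(1, dup_rel):
        length = birth_length * 2.0 ** (rel / n_cycle_frames)
        hz = preset.flip_hazard_base + preset.flip_hazard_length_slope * length
        total += min(1.0, hz * frame_interval)
    return total


def _merge_foci(
    positions: list[float], intensities: list[float], radius: float
) -> tuple[list[float], list[float]]:
    """Greedy left-to-right merge of same-marker foci closer than ``radius``.

    Merged foci are reported at their intensity-weighted mean position with
    summed intensity (models under-counting at the diffraction limit).
    """
    if len(positions) < 2:
        return positions, intensities
    order = np.argsort(positions)
    pos = [positions[i] for i in order]
    inten = [intensities[i] for i in order]
    out_p: list[float] = []
    out_i: list[float] = []
    cur_p, cur_i = pos[0], inten[0]
    for p, i in zip(pos[1:], inten[1:]):
        if p - cur_p < radius:
            w = cur_i + i
            cur_p = (cur_p * cur_i + p * i) / w
            cur_i = w
        else:
            out_p.append(cur_p)
            out_i.append(cur_i)
            cur_p, cur_i = p, i
    out_p.append(cur_p)
    out_i.append(cur_i)
    return out_p, out_i


def _spaced_subset(rng: np.random.Generator, k: int, lo: int, hi: int, sep: int) -> tuple[int, ...]:
    """Pick up to ``k`` integers in [lo, hi] pairwise separated by >= ``sep``."""
    if hi < lo or k <= 0:
        return ()
    capacity = (hi - lo) // sep + 1
    k = min(k, capacity)
    while k > 0:
        for _ in range(40):
            picks = sorted(rng.choice(np.arange(lo, hi + 1), size=k, replace=False))
            if all(b - a >= sep for a, b in zip(picks, picks[1:])):
                return tuple(int(p) for p in picks)
        k -= 1  # too crowded; drop one event and retry
    return ()


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate(
    preset: StrainPreset,
    layout: str = MOTHER_MACHINE,
    n_lineages: int = 10,
    duration: float = 600.0,
    frame_interval: Optional[float] = None,
    seed: int = 0,
    edu_pulse: Optional[tuple[float, float]] = None,
) -> SimOutput:
    """Run a seeded lineage-and-chromosome simulation.

    Parameters
    ----------
    preset
        Strain parameter bundle (validated on construction).
    layout
        ``mother_machine`` (one persistent lineage per channel, daughters
        tracked briefly before washout) or ``pad`` (all descendants tracked).
    n_lineages
        Number of channels / founder cells.
    duration
        Total imaged time in minutes; must be >= 2 * generation_time_mean.
    frame_interval
        Minutes between frames; defaults to 5 (mother machine) or 10 (pad).
    seed
        Root seed.  Per-lineage substreams are derived deterministically, so
        increasing ``n_lineages`` does not reshuffle existing lineages.
    edu_pulse
        Optional ``(pulse_start, pulse_duration)`` in minutes; flags strands
        synthesized in the window (used by :func:`apply_edu_pulse_chase`).
    """
    if layout not in (MOTHER_MACHINE, PAD):
        raise SimulationError(f"layout must be mother_machine or pad, got {layout!r}")
    if n_lineages < 1:
        raise SimulationError("n_lineages must be >= 1")
    if frame_interval is None:
        frame_interval = DEFAULT_FRAME_INTERVAL[layout]
    if frame_interval <= 0:
        raise SimulationError("frame_interval must be > 0")
    if duration < 2 * preset.generation_time_mean:
        raise SimulationError(
            "duration must be >= 2 * generation_time_mean "
            f"({2 * preset.generation_time_mean:g} min), got {duration:g}"
        )
    if edu_pulse is not None:
        p0, pd_ = edu_pulse
        if pd_ <= 0 or p0 < 0 or p0 + pd_ > duration:
            raise SimulationError("edu_pulse window must lie within the simulation duration")

    dt = float(frame_interval)
    n_frames = int(math.floor(duration / dt)) + 1
    mech = preset.mode == MECHANISTIC

    root_ss = np.random.SeedSequence(seed)
    channel_ss = root_ss.spawn(n_lineages)

    cells: list[_Cell] = []
    next_id = [0]

    def _new_id() -> int:
        next_id[0] += 1
        return next_id[0]

    def _founder_chromosome(rng: np.random.Generator, sign: int) -> ChromosomeState:
        return ChromosomeState(
            strand_template=StrandRecord(age=2, synth_start=-math.inf, synth_end=-math.inf),
            strand_nascent=StrandRecord(age=1, synth_start=-math.inf, synth_end=-math.inf),
            orientation=sign,
            template_toward=int(rng.choice([-1, 1])),
        )

    def _plan_cycle(cell: _Cell) -> None:
        """Draw every per-cycle quantity at cell creation (deterministic order)."""
        rng = cell.rng
        if cell.anucleate:
            return
        n = cell.n_cycle_frames()
        cell.dup_rel = int(np.clip(round(preset.arm_dup_frac * n), 1, n - 1))
        cell.ori_dup_rel = int(np.clip(round(preset.ori_dup_frac * n), 1, n - 1))

        # division fate of *this* cell
        p_anuc = (
            preset.p_anucleate_given_binucleate if cell.binucleate else preset.p_anucleate
        )
        cell.will_anucleate = bool(rng.random() < p_anuc)
        if cell.will_anucleate:
            new_side = (
                (1 if cell.new_pole_end == "high" else -1)
                if cell.new_pole_end is not None
                else int(rng.choice([-1, 1]))
            )
            at_new = rng.random() < preset.p_anucleate_newpole
            cell.anucleate_side = new_side if at_new else -new_side
        p_sep = (
            preset.p_ori_separated_anucleate
            if cell.will_anucleate
            else preset.p_ori_separated_normal
        )
        cell.ori_separated = bool(rng.random() < p_sep)

        if mech:
            # per-frame Bernoulli flips over the pre-duplication window
            flips = []
            for rel in range(1, cell.dup_rel):
                length = cell.birth_length * 2.0 ** (rel / n)
                hz = preset.flip_hazard_base + preset.flip_hazard_length_slope * length
                if rng.random() < min(1.0, hz * dt):
                    flips.append(rel)
            cell.flip_rels = tuple(flips)
            cell.translational = bool(rng.random() < preset.p_translational)
        else:
            k = int(rng.poisson(preset.flips_per_cycle_mean))
            cell.flip_rels = _spaced_subset(rng, k, 1, cell.dup_rel - 2, 2)
            cell.translational = bool(rng.random() < preset.p_lrlr)

        if rng.random() < preset.p_postdup_change and cell.dup_rel + 1 <= n - 1:
            cell.postdup_change_rel = int(rng.integers(cell.dup_rel + 1, n))
        cell.tsr_correct = bool(
            rng.random() < (preset.p_tsr_correct if not mech else 2.0)
        )  # mechanistic mode uses intensities + noise instead
        cell.tsr_margin = float(abs(rng.normal(30.0, 5.0)) + 5.0)

        old_side = cell.old_pole_side()
        if mech:
            chrom = cell.chromosome
            assert chrom is not None
            # flips rotate the whole nucleoid: orientation and template side
            nflips = len(cell.flip_rels)
            sign_dup = chrom.orientation * (-1) ** nflips
            template_side_dup = chrom.template_toward * (-1) ** nflips
            t_rep_start = (cell.birth_frame + preset.rep_start_frac * n) * dt
            t_rep_end = (cell.birth_frame + preset.rep_end_frac * n) * dt
            old_age = chrom.max_age
            d_old = ChromosomeState(
                strand_template=StrandRecord(
                    age=old_age + 1,
                    synth_start=chrom.strand_template.synth_start,
                    synth_end=chrom.strand_template.synth_end,
                    edu_labeled=chrom.strand_template.edu_labeled,
                ),
                strand_nascent=StrandRecord(age=0, synth_start=t_rep_start, synth_end=t_rep_end),
                orientation=sign_dup,
                template_toward=template_side_dup,
            )
            d_new = ChromosomeState(
                strand_template=StrandRecord(
                    age=chrom.strand_nascent.age + 1,
                    synth_start=chrom.strand_nascent.synth_start,
                    synth_end=chrom.strand_nascent.synth_end,
                    edu_labeled=chrom.strand_nascent.edu_labeled,
                ),
                strand_nascent=StrandRecord(age=0, synth_start=t_rep_start, synth_end=t_rep_end),
                orientation=sign_dup,
                template_toward=-template_side_dup,
            )
            if cell.translational:
                side_old = template_side_dup
            else:
                side_old = int(rng.choice([-1, 1]))
                d_new.orientation = -sign_dup  # mirror arrangement
                d_old.template_toward = int(rng.choice([-1, 1]))
                d_new.template_toward = int(rng.choice([-1, 1]))
            cell.daughters = (d_old, d_new)
            cell.daughter_sides = (side_old, -side_old)
            cell.ancestral_side = side_old
            cell.sign0 = chrom.orientation
        else:
            retained = rng.random() < preset.p_retention_old_pole
            cell.ancestral_side = old_side if retained else -old_side

        if mech and cell.edu_state != "none":
            pass  # mechanistic labels live on strands
        if not mech and cell.edu_state == "full":
            pass

    def _make_daughters(mother: _Cell, channel_stream: np.random.SeedSequence) -> list[_Cell]:
        rng = mother.rng
        L = mother.birth_length * 2.0
        eps = float(np.clip(rng.normal(0.0, preset.division_asymmetry_sd), -0.3 * L / 2, 0.3 * L / 2))
        l_low = L / 2 + eps
        l_high = L - l_low
        septum = mother.low0 + l_low  # global coordinate at division

        # final orientation identity of the mother (for inheritance draws)
        s_final = mother.sign_at(mother.n_cycle_frames())
        if mother.postdup_change_rel is not None:
            s_final = -s_final

        daughters = []
        for side, (lo, hi, blen) in (
            (-1, (mother.low0, septum, l_low)),
            (1, (septum, mother.high0, l_high)),
        ):
            d_rng = np.random.default_rng(channel_stream.spawn(1)[0])
            anuc = mother.will_anucleate and mother.anucleate_side == side
            binuc = mother.will_anucleate and mother.anucleate_side == -side
            gt = abs(rng.normal(preset.generation_time_mean, preset.generation_time_sd))
            if binuc:
                gt *= preset.anucleate_sister_gen_factor
            gt = max(gt, 2 * dt)
            n_cycle = max(2, int(round(gt / dt)))
            if side == -1:
                pal = mother.pole_age_low + 1 if mother.pole_age_low >= 0 else -1
                pah, npend = 0, "high"
            else:
                pal, npend = 0, "low"
                pah = mother.pole_age_high + 1 if mother.pole_age_high >= 0 else -1
            d = _Cell(
                cell_id=_new_id(),
                mother_id=mother.cell_id,
                channel=mother.channel,
                birth_frame=mother.div_frame,
                div_frame=mother.div_frame + n_cycle,
                tracked_until=n_frames,
                birth_length=blen,
                low0=lo,
                high0=hi,
                pole_age_low=pal,
                pole_age_high=pah,
                new_pole_end=npend,
                gen_time=gt,
                anucleate=anuc,
                binucleate=binuc,
                rng=d_rng,
            )
            # orientation / chromosome inheritance
            if mech and not anuc:
                idx = 0 if side == mother.daughter_sides[0] else 1
                chrom = mother.daughters[idx] if mother.daughters else _founder_chromosome(d_rng, 1)
                if mother.postdup_change_rel is not None:
                    chrom.orientation *= -1
                    chrom.template_toward *= -1
                d.chromosome = chrom
                d.sign0 = chrom.orientation
                if mother.will_anucleate:
                    # the anucleate sibling receives no chromosome; this
                    # daughter carries its sibling's copy as a passenger so no
                    # strand is lost at the division
                    d.passenger = mother.daughters[1 - idx]
                elif mother.passenger is not None and side == mother.daughter_sides[0]:
                    d.passenger = mother.passenger
            elif not anuc:
                if mother.translational:
                    retained = d_rng.random() < preset.p_orientation_retained_mother_daughter
                    d.sign0 = s_final if retained else -s_final
                else:
                    d.sign0 = s_final if side == -1 else -s_final
            daughters.append(d)
        return daughters

    # -- build the lineage forest ------------------------------------------
    for ch in range(n_lineages):
        ss = channel_ss[ch]
        rng = np.random.default_rng(ss.spawn(1)[0])
        gt = max(abs(rng.normal(preset.generation_time_mean, preset.generation_time_sd)), 2 * dt)
        n_cycle = max(2, int(round(gt / dt)))
        # stagger founder phase so the population is not synchronized
        birth_frame = -int(rng.integers(0, n_cycle))
        blen = max(0.8, rng.normal(preset.birth_length_mean, preset.birth_length_sd))
        high_is_old = bool(rng.random() < 0.5)
        founder = _Cell(
            cell_id=_new_id(),
            mother_id=-1,
            channel=ch,
            birth_frame=birth_frame,
            div_frame=birth_frame + n_cycle,
            tracked_until=n_frames,
            birth_length=blen,
            low0=0.0,
            high0=blen,
            pole_age_low=0 if high_is_old else 1,
            pole_age_high=1 if high_is_old else 0,
            new_pole_end="low" if high_is_old else "high",
            gen_time=gt,
            rng=np.random.default_rng(ss.spawn(1)[0]),
        )
        if mech:
            founder.chromosome = _founder_chromosome(founder.rng, int(founder.rng.choice([-1, 1])))
            founder.sign0 = founder.chromosome.orientation
        else:
            founder.sign0 = int(founder.rng.choice([-1, 1]))
        queue = [founder]
        while queue:
            cell = queue.pop(0)
            _plan_cycle(cell)
            cells.append(cell)
            divides = (
                not cell.anucleate
                and cell.div_frame < n_frames
                and cell.tracked_until >= cell.div_frame
            )
            if divides:
                cell.will_divide = True
                ds = _make_daughters(cell, ss)
                if layout == MOTHER_MACHINE:
                    # persistent lineage prefers the low (closed-end) daughter
                    low_d, high_d = ds
                    persist = low_d if not low_d.anucleate else high_d
                    for d in ds:
                        if d is not persist:
                            d.tracked_until = min(n_frames, d.birth_frame + DAUGHTER_WINDOW)
                            d.div_frame = max(d.div_frame, d.tracked_until)  # never divides in view
                            queue.append(d)
                    queue.append(persist)
                else:
                    queue.extend(ds)
            else:
                # anucleate cells linger in view but never divide
                if cell.anucleate and layout == MOTHER_MACHINE:
                    cell.tracked_until = min(n_frames, cell.birth_frame + DAUGHTER_WINDOW)

    # -- emit tables --------------------------------------------------------
    cell_rows: list[tuple] = []
    focus_rows: list[tuple] = []
    truth_rows: list[tuple] = []

    for cell in cells:
        _emit_cell(
            cell, preset, mech, dt, n_frames, cell_rows, focus_rows, truth_rows
        )

    cell_table = pd.DataFrame(cell_rows, columns=CELL_COLUMNS)
    focus_table = pd.DataFrame(focus_rows, columns=FOCUS_COLUMNS)
    truth_table = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return SimOutput(
        cell_table=cell_table,
        focus_table=focus_table,
        truth_table=truth_table,
        preset=preset,
        layout=layout,
        frame_interval=dt,
        duration=duration,
        seed=seed,
        n_frames=n_frames,
        cells=cells,
    )


def _config_string(translational: bool, identity: int) -> str:
    if translational:
        return "LRLR" if identity == 1 else "RLRL"
    return "LRRL" if identity == 1 else "RLLR"


def _emit_cell(
    cell: _Cell,
    preset: StrainPreset,
    mech: bool,
    dt: float,
    n_frames: int,
    cell_rows: list,
    focus_rows: list,
    truth_rows: list,
) -> None:
    rng = cell.rng
    first = max(cell.birth_frame, 0)
    last = min(cell.div_frame, cell.tracked_until, n_frames)  # exclusive
    if first >= last:
        return
    profiles = preset.locus_position_profiles
    miss = preset.detection_miss_rate
    old_side = cell.old_pole_side()
    new_side = -old_side

    for frame in range(first, last):
        L = cell.length_at(frame)
        half = L / 2.0
        rel = frame - cell.birth_frame
        tau = cell.tau_at(frame)
        cell_rows.append(
            (
                cell.cell_id,
                cell.mother_id,
                frame,
                round(L, 4),
                cell.channel,
                round(cell.low0, 4),
                round(cell.low0 + L, 4),
            )
        )

        if cell.anucleate:
            truth_rows.append(
                (cell.cell_id, frame, "B", 0, "", 0, cell.pole_age_low, cell.pole_age_high,
                 True, False, 0, 0)
            )
            continue

        # phase
        if tau < preset.rep_start_frac:
            phase = "B"
        elif tau < preset.rep_end_frac:
            phase = "C"
        else:
            phase = "D"

        post_dup = rel >= cell.dup_rel
        sign = cell.sign_at(rel)
        identity = sign
        if cell.postdup_change_rel is not None and rel >= cell.postdup_change_rel:
            identity = -sign
        flip_here = 1 if rel in cell.flip_rels else 0
        config = _config_string(cell.translational, identity) if post_dup else ""
        anc = cell.ancestral_side if phase == "D" else 0
        edu_side = 0
        if phase == "D":
            if mech:
                labeled = [
                    s
                    for chrom, s in zip(cell.daughters, cell.daughter_sides)
                    if any(st.edu_labeled for st in chrom.strands)
                ]
                if len(labeled) == 1:
                    edu_side = labeled[0]
                elif len(labeled) == 2:
                    edu_side = 2  # both nucleoids labeled
            else:
                if cell.edu_state == "single":
                    edu_side = -cell.ancestral_side
                elif cell.edu_state == "full":
                    edu_side = 2
        truth_rows.append(
            (cell.cell_id, frame, phase, sign, config, flip_here,
             cell.pole_age_low, cell.pole_age_high, False, cell.binucleate, anc, edu_side)
        )

        # ------------------------------------------------------------------
        # focus emission
        # ------------------------------------------------------------------
        frame_foci: dict[str, tuple[list[float], list[float]]] = {}

        def put(marker: str, pos: float, inten: float = 1000.0) -> None:
            pos = float(np.clip(pos, -0.49 * L, 0.49 * L))
            ps, its = frame_foci.setdefault(marker, ([], []))
            ps.append(pos)
            its.append(inten * (1.0 + 0.05 * rng.standard_normal()))

        # --- arm markers L3 / R3
        mfL = profiles["L3"]["mean_frac"]
        sdL = profiles["L3"]["sd_um"]
        if not post_dup:
            if mech:
                opposite = True
            else:
                opposite = rng.random() < preset.p_opposite_halves
            if opposite:
                magL = max(0.03, abs(rng.normal(mfL * half, sdL)))
                magR = max(0.03, abs(rng.normal(mfL * half, sdL)))
                put("L3", -sign * magL)
                put("R3", sign * magR)
            else:
                side = int(rng.choice([-1, 1]))
                m1, m2 = sorted(rng.uniform(0.04 * L, 0.45 * L, size=2))
                if m2 - m1 < 0.05:
                    m2 = min(m1 + 0.05, 0.46 * L)
                lo_pos, hi_pos = side * m1, side * m2
                if lo_pos > hi_pos:
                    lo_pos, hi_pos = hi_pos, lo_pos
                if sign == 1:
                    put("L3", lo_pos)
                    put("R3", hi_pos)
                else:
                    put("L3", hi_pos)
                    put("R3", lo_pos)
        else:
            qs = np.array([-0.75, -0.25, 0.25, 0.75]) * half
            qs = np.sort(qs + rng.normal(0.0, 0.06, size=4))
            if cell.translational:
                order = "LRLR" if identity == 1 else "RLRL"
            else:
                order = "LRRL" if identity == 1 else "RLLR"
            for q, m in zip(qs, order):
                put("L3" if m == "L" else "R3", q)

        # --- ori1 / ter3
        mfo = profiles["ori1"]["mean_frac"]
        sdo = profiles["ori1"]["sd_um"]
        ori_center = old_side * mfo * half
        if rel < cell.ori_dup_rel:
            put("ori1", rng.normal(ori_center, sdo))
        else:
            sep = 1.0 if cell.ori_separated else 0.15
            c = ori_center if abs(ori_center) + sep / 2 < 0.45 * L else 0.0
            put("ori1", c - sep / 2 + rng.normal(0, 0.02))
            put("ori1", c + sep / 2 + rng.normal(0, 0.02))
        mft = profiles["ter3"]["mean_frac"]
        sdt = profiles["ter3"]["sd_um"]
        put("ter3", rng.normal(new_side * (1.0 - tau) * mft * half, sdt))

        # --- replisome / clamp foci during replication
        if phase == "C":
            mfn = profiles["dnaN"]["mean_frac"]
            sdn = profiles["dnaN"]["sd_um"]
            pos_n = float(np.clip(rng.normal(old_side * mfn * half, sdn), -0.45 * L, 0.45 * L))
            om = preset.colocal_offset_model
            if mech:
                p_near = om.get("p_near", 0.588)
            else:
                p_near = preset.p_colocal
            if rng.random() < p_near:
                d = rng.uniform(0.0, om["d_near_max"])
            else:
                d = rng.uniform(om["d_far_min"], om["d_far_max"])
            direction = 1.0 if rng.random() < 0.5 else -1.0
            if abs(pos_n + direction * d) > 0.48 * L:
                direction = -direction
            put("dnaN", pos_n)
            put("dnaQ", pos_n + direction * d)

        # --- polar Tsr intensities
        if mech:
            i_low = 100.0 + preset.tsr_rate * max(cell.pole_age_low, 0) + rng.normal(
                0.0, preset.tsr_noise_sd
            )
            i_high = 100.0 + preset.tsr_rate * max(cell.pole_age_high, 0) + rng.normal(
                0.0, preset.tsr_noise_sd
            )
        else:
            hi_int = 100.0 + cell.tsr_margin
            lo_int = 100.0 - cell.tsr_margin
            if cell.tsr_correct:
                i_low, i_high = (hi_int, lo_int) if old_side == -1 else (lo_int, hi_int)
            else:
                i_low, i_high = (lo_int, hi_int) if old_side == -1 else (hi_int, lo_int)
        frame_foci.setdefault("tsr", ([], []))[0].extend([-0.499 * L, 0.499 * L])
        frame_foci["tsr"][1].extend([i_low, i_high])

        # observation model: merge within the diffraction limit, then misses
        for marker, (ps, its) in frame_foci.items():
            if marker != "tsr":
                ps, its = _merge_foci(ps, its, preset.merge_radius)
            for p, i in zip(ps, its):
                if miss > 0 and marker != "tsr" and rng.random() < miss:
                    continue
                focus_rows.append((cell.cell_id, frame, marker, round(p, 4), round(i, 2)))


# ---------------------------------------------------------------------------
# EdU pulse-chase
# ---------------------------------------------------------------------------

def apply_edu_pulse_chase(
    sim: SimOutput,
    pulse_start: float,
    pulse_duration: float,
    chase_duration: float,
) -> SimOutput:
    """Label strands synthesized in the pulse window and emit EdU/DAPI channels.

    DAPI nucleoid foci are emitted for every non-anucleate cell at frames after
    the chase (one centred nucleoid in B/C, two at the quarter positions in D).
    EdU foci are emitted only on labeled nucleoids.  Returns a new
    :class:`SimOutput` sharing the cell table.
    """
    if pulse_duration <= 0:
        raise SimulationError("pulse_duration must be > 0")
    if pulse_start < 0 or pulse_start + pulse_duration > sim.duration:
        raise SimulationError("pulse window lies outside the simulation duration")
    if chase_duration < sim.preset.generation_time_mean:
        raise SimulationError("chase_duration must cover at least one full generation")

    dt = sim.frame_interval
    observe_frame = int(math.ceil((pulse_start + pulse_duration + chase_duration) / dt))
    mech = sim.preset.mode == MECHANISTIC
    pulse_end = pulse_start + pulse_duration

    if mech:
        for cell in sim.cells:
            for chrom in (cell.chromosome, *cell.daughters):
                if chrom is None:
                    continue
                for st in chrom.strands:
                    st.edu_labeled = (
                        st.synth_start < pulse_end and st.synth_end > pulse_start
                    )
    else:
        # post-hoc label propagation down the lineage (cells are stored
        # mothers-before-daughters): a cell replicating during the pulse is
        # fully labeled; after one more round each daughter carries the label
        # on a single nucleoid; thereafter the label follows the chromosome
        # opposite the mother's ancestral side
        by_id = {c.cell_id: c for c in sim.cells}
        for cell in sim.cells:
            if cell.anucleate:
                cell.edu_state = "none"
                continue
            n = cell.n_cycle_frames()
            t_rs = (cell.birth_frame + sim.preset.rep_start_frac * n) * dt
            t_re = (cell.birth_frame + sim.preset.rep_end_frac * n) * dt
            if t_rs < pulse_end and t_re > pulse_start:
                cell.edu_state = "full"
                continue
            mother = by_id.get(cell.mother_id)
            if mother is None or mother.anucleate:
                cell.edu_state = "none"
            elif mother.edu_state == "full":
                cell.edu_state = "single"
            elif mother.edu_state == "single":
                side = 1 if cell.low0 > mother.low0 else -1
                cell.edu_state = "single" if side == -mother.ancestral_side else "none"
            else:
                cell.edu_state = "none"

    focus_rows: list[tuple] = []
    truth_updates: dict[tuple[int, int], int] = {}
    for cell in sim.cells:
        if cell.anucleate:
            continue
        first = max(cell.birth_frame, 0, observe_frame)
        last = min(cell.div_frame, cell.tracked_until, sim.n_frames)
        rng = np.random.default_rng(
            np.random.SeedSequence([sim.seed, 7_777, cell.cell_id])
        )
        for frame in range(first, last):
            L = cell.length_at(frame)
            tau = cell.tau_at(frame)
            if tau < sim.preset.rep_end_frac:
                focus_rows.append((cell.cell_id, frame, "dapi", 0.0, 500.0))
                continue
            # D period: two nucleoids at the quarter positions
            for s in (-1, 1):
                focus_rows.append((cell.cell_id, frame, "dapi", round(s * L / 4, 4), 500.0))
            if mech:
                labeled_sides = [
                    s
                    for chrom, s in zip(cell.daughters, cell.daughter_sides)
                    if any(st.edu_labeled for st in chrom.strands)
                ]
            else:
                if cell.edu_state == "single":
                    labeled_sides = [-cell.ancestral_side]
                elif cell.edu_state == "full":
                    labeled_sides = [-1, 1]
                else:
                    labeled_sides = []
            if len(labeled_sides) == 1:
                truth_updates[(cell.cell_id, frame)] = labeled_sides[0]
            elif len(labeled_sides) == 2:
                truth_updates[(cell.cell_id, frame)] = 2
            for s in labeled_sides:
                c = s * L / 4
                for off in (-0.12, 0.12):
                    focus_rows.append(
                        (cell.cell_id, frame, "edu",
                         round(float(np.clip(c + off + rng.normal(0, 0.03), -0.49 * L, 0.49 * L)), 4),
                         800.0)
                    )

    new_focus = pd.concat(
        [sim.focus_table, pd.DataFrame(focus_rows, columns=FOCUS_COLUMNS)],
        ignore_index=True,
    )
    truth = sim.truth_table.copy()
    if truth_updates:
        key = list(zip(truth["cell_id"], truth["frame"]))
        truth["edu_side"] = [truth_updates.get(k, e) for k, e in zip(key, truth["edu_side"])]
    return SimOutput(
        cell_table=sim.cell_table,
        focus_table=new_focus,
        truth_table=truth,
        preset=sim.preset,
        layout=sim.layout,
        frame_interval=sim.frame_interval,
        duration=sim.duration,
        seed=sim.seed,
        n_frames=sim.n_frames,
        cells=sim.cells,
    )
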