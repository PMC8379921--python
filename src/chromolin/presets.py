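"""Strain presets and their validation.

A :class:`StrainPreset` bundles every parameter the simulator needs, in one of
two modes:

``mechanistic``
    Observables (configuration statistics, flips, strand retention) *emerge*
    from strand-level rules: per-frame orientation-flip hazard, a
    translational-vs-mirror segregation choice, and semiconservative strand
    bookkeeping.

``phenomenological``
    Each headline observable is governed by a direct probability parameter
    (``p_opposite_halves``, ``p_lrlr``, ...), so any pipeline statistic can be
    checked against the parameter that generated it.

Exactly one mode is active; parameters belonging to the other mode must be
left unset, and the loader rejects mixed specifications.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Optional

import yaml

MECHANISTIC = "mechanistic"
PHENOMENOLOGICAL = "phenomenological"

#: markers treated as chromosomal FROS labels (used by anucleate detection)
FROS_MARKERS = ("L3", "R3", "ori1", "ter3")

_MECH_ONLY = ("flip_hazard_base", "flip_hazard_length_slope", "p_translational")
_PHEN_ONLY = (
    "p_opposite_halves",
    "p_lrlr",
    "p_orientation_retained_mother_daughter",
    "flips_per_cycle_mean",
    "p_colocal",
    "p_retention_old_pole",
    "p_tsr_correct",
)


class PresetError(ValueError):
    """Raised for invalid or mixed-mode preset specifications."""


def _default_locus_profiles() -> dict[str, dict[str, float]]:
    # mean_frac: |mean signed position| as a fraction of the cell half-length;
    # sd_um: Gaussian spread around it.
    return {
        "L3": {"mean_frac": 0.5, "sd_um": 0.10},
        "R3": {"mean_frac": 0.5, "sd_um": 0.10},
        "ori1": {"mean_frac": 0.0, "sd_um": 0.12},
        "ter3": {"mean_frac": 0.5, "sd_um": 0.12},
        "dnaN": {"mean_frac": 0.0, "sd_um": 0.285},
        "dnaQ": {"mean_frac": 0.0, "sd_um": 0.285},
    }


def _default_colocal_offset() -> dict[str, float]:
    # Distance (um) from a dnaQ focus to its dnaN partner: a near component
    # under the diffraction limit and a displaced component beyond it.
    return {"d_near_max": 0.28, "d_far_min": 0.33, "d_far_max": 1.2}


@dataclass(frozen=True)
class StrainPreset:
    """Named parameter bundle for one strain in one simulator mode."""

    name: str
    mode: str

    # growth / division
    generation_time_mean: float = 150.0  # minutes
    generation_time_sd: float = 10.0
    birth_length_mean: float = 2.5  # um
    birth_length_sd: float = 0.15
    division_asymmetry_sd: float = 0.12  # um, septum offset from midcell

    # anucleate-division machinery
    p_anucleate: float = 0.0
    p_anucleate_newpole: float = 0.744
    p_anucleate_given_binucleate: float = 0.091
    anucleate_sister_gen_factor: float = 1.14  # 72/63 min slowdown

    # cell-cycle landmarks (fractions of the cycle)
    rep_start_frac: float = 0.10
    rep_end_frac: float = 0.75
    arm_dup_frac: float = 0.65  # L3/R3 duplication
    ori_dup_frac: float = 0.25

    # ori focus separation behaviour prior to division
    p_ori_separated_normal: float = 0.9
    p_ori_separated_anucleate: float = 0.2

    # observation model
    locus_position_profiles: dict[str, dict[str, float]] = field(
        default_factory=_default_locus_profiles
    )
    colocal_offset_model: dict[str, float] = field(default_factory=_default_colocal_offset)
    tsr_rate: float = 50.0  # intensity units per pole-age generation
    tsr_noise_sd: float = 0.0
    detection_miss_rate: float = 0.0
    merge_radius: float = 0.3  # um, diffraction limit

    # post-duplication configuration change per cycle (both modes)
    p_postdup_change: float = 0.0

    # mechanistic-only
    flip_hazard_base: Optional[float] = None  # events / min
    flip_hazard_length_slope: Optional[float] = None  # events / min / um
    p_translational: Optional[float] = None

    # phenomenological-only
    p_opposite_halves: Optional[float] = None
    p_lrlr: Optional[float] = None
    p_orientation_retained_mother_daughter: Optional[float] = None
    flips_per_cycle_mean: Optional[float] = None
    p_colocal: Optional[float] = None
    p_retention_old_pole: Optional[float] = None
    p_tsr_correct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in (MECHANISTIC, PHENOMENOLOGICAL):
            raise PresetError(f"mode must be mechanistic or phenomenological, got {self.mode!r}")
        if self.generation_time_mean <= 0:
            raise PresetError("generation_time_mean must be > 0")
        for fname in (
            "generation_time_sd",
            "birth_length_sd",
            "division_asymmetry_sd",
            "tsr_rate",
            "tsr_noise_sd",
            "merge_radius",
        ):
            if getattr(self, fname) < 0:
                raise PresetError(f"{fname} must be >= 0")
        for fname in (
            "p_anucleate",
            "p_anucleate_newpole",
            "p_anucleate_given_binucleate",
            "p_ori_separated_normal",
            "p_ori_separated_anucleate",
            "detection_miss_rate",
            "p_postdup_change",
        ):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise PresetError(f"{fname} must be in [0, 1], got {v}")
        if not 0 < self.arm_dup_frac <= 1 or not 0 < self.ori_dup_frac <= 1:
            raise PresetError("duplication fractions must be in (0, 1]")

        active = _MECH_ONLY if self.mode == MECHANISTIC else _PHEN_ONLY
        inactive = _PHEN_ONLY if self.mode == MECHANISTIC else _MECH_ONLY
        for fname in inactive:
            if getattr(self, fname) is not None:
                raise PresetError(
                    f"{fname} belongs to the inactive mode and must be unset in "
                    f"{self.mode} presets (mixed-mode specification)"
                )
        for fname in active:
            if getattr(self, fname) is None:
                raise PresetError(f"{fname} is required in {self.mode} mode")
        for fname in active:
            v = getattr(self, fname)
            if fname.startswith("p_") and not 0.0 <= v <= 1.0:
                raise PresetError(f"{fname} must be in [0, 1], got {v}")
            if not fname.startswith("p_") and fname != "flip_hazard_length_slope" and v < 0:
                raise PresetError(f"{fname} must be >= 0")

    def replace(self, **changes: Any) -> "StrainPreset":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        # drop inactive-mode Nones for a clean round-trippable config
        return {k: v for k, v in d.items() if v is not None}


def preset_from_dict(d: dict[str, Any]) -> StrainPreset:
    """Build a preset from a plain mapping, rejecting unknown keys."""
    known = {f.name for f in dataclasses.fields(StrainPreset)}
    unknown = set(d) - known
    if unknown:
        raise PresetError(f"unknown preset fields: {sorted(unknown)}")
    return StrainPreset(**d)


def save_preset(preset: StrainPreset, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(preset.to_dict(), fh, sort_keys=True)


def load_preset(path: str) -> StrainPreset:
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise PresetError(f"preset file {path} does not contain a mapping")
    return preset_from_dict(d)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def _phen(name: str, **kw: Any) -> StrainPreset:
    return StrainPreset(name=name, mode=PHENOMENOLOGICAL, **kw)


def _wt_phen() -> StrainPreset:
    return _phen(
        "WT",
        generation_time_mean=150.0,
        generation_time_sd=10.0,
        p_anucleate=0.0013,
        p_opposite_halves=0.978,
        p_lrlr=0.731,
        p_orientation_retained_mother_daughter=0.914,
        flips_per_cycle_mean=0.08,
        p_colocal=0.588,
        p_retention_old_pole=0.713,
        p_tsr_correct=0.992,
        p_postdup_change=0.003,
    )


def _dmukb_phen() -> StrainPreset:
    profiles = _default_locus_profiles()
    profiles["ori1"] = {"mean_frac": 0.35, "sd_um": 0.25}  # old-pole biased
    profiles["dnaN"] = {"mean_frac": 0.35, "sd_um": 0.40}
    profiles["dnaQ"] = {"mean_frac": 0.35, "sd_um": 0.40}
    # p_anucleate is the single-chromosome per-division probability; the
    # population-level rate mixes in two-chromosome mothers (which divide
    # anucleate at p_anucleate_given_binucleate), so 0.169 yields an aggregate
    # anucleate-division rate of 0.157: r = p1 / (1 + p1 - p2).
    return _phen(
        "dmukB",
        generation_time_mean=63.0,
        generation_time_sd=5.0,
        p_anucleate=0.169,
        p_anucleate_newpole=0.744,
        p_anucleate_given_binucleate=0.091,
        p_ori_separated_normal=0.7,
        p_ori_separated_anucleate=0.2,
        locus_position_profiles=profiles,
        p_opposite_halves=0.566,
        p_lrlr=0.477,
        p_orientation_retained_mother_daughter=0.5,
        flips_per_cycle_mean=0.3,
        p_colocal=0.784,
        p_retention_old_pole=0.485,
        p_tsr_correct=0.992,
        p_postdup_change=0.02,
    )


def _dmatp_phen() -> StrainPreset:
    profiles = _default_locus_profiles()
    # arm markers collapse toward the cell centre; arm distance halves
    profiles["L3"] = {"mean_frac": 0.25, "sd_um": 0.10}
    profiles["R3"] = {"mean_frac": 0.25, "sd_um": 0.10}
    profiles["dnaN"] = {"mean_frac": 0.0, "sd_um": 0.786}
    profiles["dnaQ"] = {"mean_frac": 0.0, "sd_um": 0.484}
    return _phen(
        "dmatP",
        generation_time_mean=150.0,
        generation_time_sd=10.0,
        p_anucleate=0.003,
        locus_position_profiles=profiles,
        p_opposite_halves=0.657,
        p_lrlr=0.802,
        p_orientation_retained_mother_daughter=0.322,
        flips_per_cycle_mean=0.78,
        p_colocal=0.508,
        p_retention_old_pole=0.462,
        p_tsr_correct=0.992,
        p_postdup_change=0.062,
    )


def _wt_variant(name: str, p_retention: float) -> StrainPreset:
    return _wt_phen().replace(name=name, p_retention_old_pole=p_retention)


def _mech(name: str, hazard_slope: float, p_translational: float, **kw: Any) -> StrainPreset:
    return StrainPreset(
        name=name,
        mode=MECHANISTIC,
        birth_length_mean=2.0,
        flip_hazard_base=0.0,
        flip_hazard_length_slope=hazard_slope,
        p_translational=p_translational,
        **kw,
    )


# Hazard slopes chosen so the expected per-cycle flip count over the
# pre-duplication window of an average cell (length 2 um at birth, doubling in
# 150 min, duplication at 65% of the cycle) matches each strain's per-cycle
# flip mean; see simulate.expected_flips_per_cycle for the closed form.
_REGISTRY = {
    (PHENOMENOLOGICAL, "WT"): _wt_phen,
    (PHENOMENOLOGICAL, "dmukB"): _dmukb_phen,
    (PHENOMENOLOGICAL, "dmatP"): _dmatp_phen,
    (PHENOMENOLOGICAL, "matPdC20"): lambda: _wt_variant("matPdC20", 0.710),
    (PHENOMENOLOGICAL, "dzapB"): lambda: _wt_variant("dzapB", 0.718),
    (PHENOMENOLOGICAL, "ddam"): lambda: _wt_variant("ddam", 0.699),
    (PHENOMENOLOGICAL, "dseqA"): lambda: _wt_variant("dseqA", 0.676),
    (MECHANISTIC, "WT"): lambda: _mech(
        "WT", hazard_slope=0.000368, p_translational=0.731, p_postdup_change=0.003
    ),
    (MECHANISTIC, "dmatP"): lambda: _mech(
        "dmatP", hazard_slope=0.003586, p_translational=0.802, p_postdup_change=0.062
    ),
    (MECHANISTIC, "dmukB"): lambda: _mech(
        "dmukB",
        hazard_slope=0.000368,
        p_translational=0.5,
        generation_time_mean=63.0,
        generation_time_sd=5.0,
        p_anucleate=0.157,
    ),
}


def available_presets() -> list[tuple[str, str]]:
    """List (name, mode) pairs in the registry."""
    return sorted((name, mode) for (mode, name) in _REGISTRY)


def get_preset(name: str, mode: str = PHENOMENOLOGICAL) -> StrainPreset:
    """Look up a registered strain preset by name and mode."""
    try:
        return _REGISTRY[(mode, name)]()
    except KeyError:
        raise PresetError(
            f"no preset {name!r} in mode {mode!r}; available: {available_presets()}"
        ) from None
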