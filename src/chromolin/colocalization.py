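"""Nearest-focus distances, diffraction-limit colocalization fractions, and
localization profiles with FWHM at selected cell lengths."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DIFFRACTION_LIMIT_UM = 0.3


@dataclass
class DistancePairSet:
    """Per source focus: the 1D distance to the nearest same-cell target
    focus, within one frame.  Cell-frames lacking any target focus contribute
    censored entries (counted, never zero-filled)."""

    source: str
    target: str
    table: pd.DataFrame  # cell_id, frame, source_pos, distance_um
    n_censored: int = 0

    @property
    def distances(self) -> np.ndarray:
        return self.table["distance_um"].to_numpy(float)


def nearest_distances(
    focus_table: pd.DataFrame, source: str, target: str
) -> DistancePairSet:
    """For each source focus, the distance to the nearest target focus in the
    same cell and frame (1D, along the long axis)."""
    markers = set(focus_table["marker"].unique())
    for m in (source, target):
        if m not in markers:
            raise KeyError(f"marker {m!r} absent from focus table")
    src = focus_table[focus_table["marker"] == source]
    tgt = focus_table[focus_table["marker"] == target]
    tgt_by_cf = tgt.groupby(["cell_id", "frame"])["position_um"].apply(
        lambda s: np.sort(s.to_numpy(float))
    )
    rows = []
    n_censored = 0
    for (cid, frame), grp in src.groupby(["cell_id", "frame"]):
        try:
            tpos = tgt_by_cf.loc[(cid, frame)]
        except KeyError:
            n_censored += len(grp)
            continue
        for p in grp["position_um"].to_numpy(float):
            i = np.searchsorted(tpos, p)
            cands = []
            if i < len(tpos):
                cands.append(abs(tpos[i] - p))
            if i > 0:
                cands.append(abs(p - tpos[i - 1]))
            rows.append((cid, frame, p, min(cands)))
    table = pd.DataFrame(rows, columns=["cell_id", "frame", "source_pos", "distance_um"])
    return DistancePairSet(source=source, target=target, table=table, n_censored=n_censored)


def colocal_fraction(
    pairs: DistancePairSet, threshold: float = DIFFRACTION_LIMIT_UM
) -> tuple[float, int, np.ndarray]:
    """Fraction of source foci within ``threshold`` of the nearest target
    focus, plus the sorted distances (the cumulative distribution support).

    Monotone nondecreasing in the threshold by construction.
    """
    d = pairs.distances
    if d.size == 0:
        raise ValueError(
            f"no {pairs.source}->{pairs.target} pairs; colocal fraction undefined"
        )
    frac = float((d <= threshold).mean())
    return frac, int(d.size), np.sort(d)


@dataclass
class LocalizationProfile:
    marker: str
    edges: np.ndarray
    counts: np.ndarray
    smoothed: np.ndarray
    fwhm_um: float
    n_foci: int
    multimodal_flag: bool = False
    half_crossings: list = field(default_factory=list)


def _fwhm(edges: np.ndarray, values: np.ndarray) -> tuple[float, bool, list[float]]:
    """Full width at half maximum via linear interpolation of the half-max
    crossings.  More than two crossings -> widest span, flagged."""
    centers = (edges[:-1] + edges[1:]) / 2.0
    vmax = values.max()
    if vmax <= 0:
        return 0.0, False, []
    half = vmax / 2.0
    above = values >= half
    crossings: list[float] = []
    for i in range(len(values) - 1):
        a, b = values[i], values[i + 1]
        if (a < half) != (b < half):
            t = (half - a) / (b - a)
            crossings.append(float(centers[i] + t * (centers[i + 1] - centers[i])))
    if not crossings:
        # distribution entirely above half max across its support
        idx = np.nonzero(above)[0]
        return float(centers[idx[-1]] - centers[idx[0]]) if idx.size else 0.0, False, []
    if len(crossings) == 1:
        idx = np.nonzero(above)[0]
        lo = min(crossings[0], centers[idx[0]])
        hi = max(crossings[0], centers[idx[-1]])
        return hi - lo, False, crossings
    width = max(crossings) - min(crossings)
    return width, len(crossings) > 2, crossings


def profile_at_lengths(
    focus_table: pd.DataFrame,
    cell_table: pd.DataFrame,
    marker: str,
    length_window: tuple[float, float] = (3.3, 3.7),
    pos_bin: float = 0.05,
    smooth_bins: int = 3,
    min_foci: int = 100,
) -> LocalizationProfile:
    """Signed-position histogram and FWHM for foci in cells within a length
    window (e.g. intermediate-length cells in mid-replication)."""
    lo, hi = length_window
    if not lo < hi:
        raise ValueError("length_window must satisfy lo < hi")
    lengths = cell_table.set_index(["cell_id", "frame"])["length_um"]
    sub = focus_table[focus_table["marker"] == marker]
    if sub.empty:
        raise KeyError(f"marker {marker!r} absent from focus table")
    key = pd.MultiIndex.from_frame(sub[["cell_id", "frame"]])
    L = lengths.reindex(key).to_numpy(float)
    in_window = (L >= lo) & (L <= hi)
    pos = sub["position_um"].to_numpy(float)[in_window]
    if pos.size < min_foci:
        raise ValueError(
            f"only {pos.size} {marker} foci in window {length_window}; "
            f"need >= {min_foci} for a stable FWHM"
        )
    half_span = hi / 2.0 + pos_bin
    edges = np.arange(-half_span, half_span + pos_bin, pos_bin)
    counts, _ = np.histogram(pos, bins=edges)
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        smoothed = np.convolve(counts.astype(float), kernel, mode="same")
    else:
        smoothed = counts.astype(float)
    width, flagged, crossings = _fwhm(edges, smoothed)
    return LocalizationProfile(
        marker=marker,
        edges=edges,
        counts=counts,
        smoothed=smoothed,
        fwhm_um=width,
        n_foci=int(pos.size),
        multimodal_flag=flagged,
        half_crossings=crossings,
    )


def replication_gated_frames(focus_table: pd.DataFrame, marker: str = "dnaQ") -> pd.DataFrame:
    """Per cell: the frame interval between the first and last focus of
    ``marker`` (the operational replication window)."""
    sub = focus_table[focus_table["marker"] == marker]
    g = sub.groupby("cell_id")["frame"].agg(["min", "max"]).reset_index()
    return g.rename(columns={"min": "first_frame", "max": "last_frame"})
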