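"""Two-dimensional grid algorithm for exposed-water (pore) area.

The monolayer's integrity is charted by comparing head-group positions
with an M x M occupancy grid whose resolution matches the number of
selected atoms (M^2 ~ N).  Atoms are snapped to their nearest grid point
by dividing the coordinates by the grid spacing and rounding; the pore
area at a time step is the proportion of grid points left unoccupied.
No distances between atoms and grid points are ever computed, which is
what makes the method fast on long trajectories.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .datatypes import Frame, GridSpec, PoreSeries, RuptureEvent, SyntheticTrajectory

#: Head-group atom selection per lipid class: the galactosyl oxygens for
#: the glycolipid, phosphorus and nitrogen for the phospholipid.
_SELECTION_PREFIXES = {
    "glycolipid": ("O",),
    "phospholipid": ("P", "N"),
}


def select_headgroup_positions(frame_atoms, lipid_type: str):
    """Pick the x, y coordinates of the head-group marker atoms.

    ``frame_atoms`` may be a :class:`Frame` (synthetic data: positions
    are already the 2-D head markers, returned unchanged) or a pandas
    DataFrame with columns ``name``, ``x``, ``y`` from a coordinate file.
    Selection is by atom-name prefix: oxygens for ``glycolipid``,
    phosphorus/nitrogen for ``phospholipid``.
    """
    if lipid_type not in _SELECTION_PREFIXES:
        raise ValueError(f"unknown lipid_type {lipid_type!r}")
    if isinstance(frame_atoms, Frame):
        return frame_atoms.positions
    df = frame_atoms
    prefixes = _SELECTION_PREFIXES[lipid_type]
    names = df["name"].astype(str).str.strip().str.upper()
    mask = names.str.startswith(prefixes)
    if not mask.any():
        raise ValueError(f"no atoms match the {lipid_type} head-group selection")
    return df.loc[mask, ["x", "y"]].to_numpy(dtype=float)


def build_grid(n_atoms: int, box_width: float, offset_fraction: float = 0.01) -> GridSpec:
    """Grid with M = round(sqrt(n_atoms)), slightly inset from the walls."""
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    if not 0 <= offset_fraction < 0.5:
        raise ValueError("offset_fraction must lie in [0, 0.5)")
    M = max(1, round(math.sqrt(n_atoms)))
    offset = offset_fraction * box_width
    spacing = (box_width - 2 * offset) / M
    return GridSpec(M=M, spacing=spacing, offset=offset)


def pore_fraction(
    positions,
    grid: GridSpec,
    box_width: float,
    mode: str = "round",
) -> float:
    """Proportion of unoccupied grid points for one frame.

    Each atom is assigned the integer index ``(x - offset) / spacing``
    rounded to nearest (ties to even) in ``round`` mode, or truncated in
    ``truncate`` mode, then clipped to [0, M-1].  Grid points never see
    an explicit distance computation.
    """
    if mode not in ("round", "truncate"):
        raise ValueError("mode must be 'round' or 'truncate'")
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.size == 0:
        warnings.warn("empty position set: the whole surface is water", stacklevel=2)
        return 1.0
    scaled = (positions - grid.offset) / grid.spacing
    idx = np.rint(scaled).astype(int) if mode == "round" else np.trunc(scaled).astype(int)
    idx = np.clip(idx, 0, grid.M - 1)
    flat = idx[:, 0] * grid.M + idx[:, 1]
    occupied = len(np.unique(flat))
    return 1.0 - occupied / grid.M**2


def pore_area_series(
    traj: SyntheticTrajectory,
    grid_policy: str = "per_frame",
    offset_fraction: float = 0.01,
    mode: str = "round",
    lipid_type: str | None = None,
) -> PoreSeries:
    """Pore fraction for every frame of a trajectory.

    ``per_frame`` rebuilds the grid from the instantaneous box width
    (constant M, rescaled spacing) so coverage is measured relative to
    the current area; ``fixed_first_frame`` freezes the first frame's
    grid, so expansion itself registers as exposure.
    """
    if grid_policy not in ("per_frame", "fixed_first_frame"):
        raise ValueError("grid_policy must be 'per_frame' or 'fixed_first_frame'")
    frames = traj.frames
    if not frames:
        raise ValueError("trajectory has no frames")
    n_atoms = frames[0].n_lipids
    if any(f.n_lipids != n_atoms for f in frames):
        raise ValueError("inconsistent atom counts across frames")
    grid0 = build_grid(n_atoms, frames[0].h_xy, offset_fraction)
    fractions = np.empty(len(frames))
    for i, frame in enumerate(frames):
        grid = (
            grid0
            if grid_policy == "fixed_first_frame"
            else build_grid(n_atoms, frame.h_xy, offset_fraction)
        )
        fractions[i] = pore_fraction(frame.positions, grid, frame.h_xy, mode=mode)
    return PoreSeries(
        times=traj.times, pore_fraction=fractions, grid=grid0, grid_policy=grid_policy
    )


def detect_rupture(
    series: PoreSeries, threshold: float = 0.10, min_consecutive: int = 3
) -> RuptureEvent | None:
    """First time the pore fraction holds >= threshold for a run of frames.

    ``min_consecutive`` debounces single-frame spikes; returns ``None``
    when the coverage never stays above threshold.
    """
    if len(series.times) == 0:
        raise ValueError("empty pore series")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if min_consecutive < 1:
        raise ValueError("min_consecutive must be >= 1")
    above = series.pore_fraction >= threshold
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= min_consecutive:
            start = i - min_consecutive + 1
            return RuptureEvent(
                time=float(series.times[start]),
                pore_fraction_at_event=float(series.pore_fraction[start]),
                threshold_used=threshold,
            )
    return None


def pore_series_frame(series: PoreSeries) -> pd.DataFrame:
    """Tabular view (time ps, pore_fraction) for serialization."""
    return pd.DataFrame({"time_ps": series.times, "pore_fraction": series.pore_fraction})
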