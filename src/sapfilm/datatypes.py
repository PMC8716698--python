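"""Shared domain types for the monolayer analysis pipeline.

These are deliberately thin containers: each stage validates its own
physics, the types only enforce structural invariants (array lengths,
positivity, orderings) so that a malformed object fails early rather
than deep inside an estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .units import DEFAULT_TEMPERATURE_K, wrap_coordinates

GLYCOLIPID = "glycolipid"
PHOSPHOLIPID = "phospholipid"
LIPID_MODES = (GLYCOLIPID, PHOSPHOLIPID)


@dataclass
class Frame:
    """One time step of head-group positions in a square lateral box.

    Attributes
    ----------
    time : float
        Frame time, ps.
    positions : (N, 2) ndarray
        Lateral head-group coordinates, nm, wrapped into [0, h_xy).
    h_xy : float
        Lateral box width, nm (square box).
    h_z : float
        Box height (normal direction), nm.
    """

    time: float
    positions: np.ndarray
    h_xy: float
    h_z: float

    def __post_init__(self):
        if self.h_xy <= 0 or self.h_z <= 0:
            raise ValueError("box dimensions must be positive")
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size and self.positions.shape[1] != 2:
            raise ValueError("positions must be (N, 2)")
        self.positions = wrap_coordinates(self.positions, self.h_xy)

    @property
    def n_lipids(self) -> int:
        return len(self.positions)


@dataclass
class SyntheticTrajectory:
    """Ordered frames from one synthetic pulling run."""

    frames: list[Frame]
    external_pressure: float  # MPa, <= 0 for pulling
    lipid_mode: str
    n_lipids_per_monolayer: int
    seed: int
    ruptured: bool = False
    rupture_time: Optional[float] = None  # ps, generator-internal flag
    pore_fraction_geometric: Optional[np.ndarray] = None  # disk-union coverage

    def __post_init__(self):
        if self.lipid_mode not in LIPID_MODES:
            raise ValueError(f"lipid_mode must be one of {LIPID_MODES}")
        if self.n_lipids_per_monolayer < 1:
            raise ValueError("n_lipids_per_monolayer must be >= 1")
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


@dataclass
class PressureTensorSeries:
    """Diagonal pressure-tensor components over time for a slab box."""

    times: np.ndarray  # ps
    Px: np.ndarray  # MPa
    Py: np.ndarray  # MPa
    Pz: np.ndarray  # MPa
    h_z: float  # nm
    n_interfaces: int = 2

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.Px = np.asarray(self.Px, dtype=float)
        self.Py = np.asarray(self.Py, dtype=float)
        self.Pz = np.asarray(self.Pz, dtype=float)
        n = len(self.times)
        if not (len(self.Px) == len(self.Py) == len(self.Pz) == n):
            raise ValueError("component arrays must have equal length")
        if self.n_interfaces not in (1, 2):
            raise ValueError("n_interfaces must be 1 or 2")
        if self.h_z <= 0:
            raise ValueError("h_z must be positive")


@dataclass
class DensityProfile:
    """Binned density along the box normal (slab geometry)."""

    z_centers: np.ndarray  # nm
    density: np.ndarray  # arbitrary units
    h_z: float  # nm

    def __post_init__(self):
        self.z_centers = np.asarray(self.z_centers, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if len(self.z_centers) != len(self.density):
            raise ValueError("z_centers and density must have equal length")
        if len(self.z_centers) > 1:
            dz = np.diff(self.z_centers)
            if not np.allclose(dz, dz[0], rtol=1e-6, atol=1e-9):
                raise ValueError("slice spacing must be uniform")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    @property
    def n_slices(self) -> int:
        return len(self.z_centers)


@dataclass
class TensionEstimate:
    """Surface-tension time series from one estimator."""

    method: str  # "pressure_tensor" | "capillary_wave"
    times: np.ndarray  # ps
    gamma: np.ndarray  # mN/m
    cumulative_gamma: Optional[np.ndarray] = None  # running mean, PT only
    chunk_length: Optional[float] = None  # ps, CW only
    gamma_top: Optional[np.ndarray] = None  # CW per-interface estimates
    gamma_bottom: Optional[np.ndarray] = None
    gamma_sd: Optional[np.ndarray] = None  # within-chunk spread, CW only

    def __post_init__(self):
        if self.method not in ("pressure_tensor", "capillary_wave"):
            raise ValueError("unknown estimator method")
        self.times = np.asarray(self.times, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if not np.all(np.isfinite(self.gamma)):
            raise ValueError("gamma must be finite")
        if self.method == "capillary_wave" and self.cumulative_gamma is not None:
            raise ValueError("cumulative series is defined only for pressure_tensor")


@dataclass
class Isotherm:
    """Binned surface-pressure-area points for one external pressure.

    ``points`` columns: A (nm^2 per lipid), Pi (mN/m), sd (mN/m), n_samples.
    """

    pressure_label: float  # MPa
    points: pd.DataFrame

    def __post_init__(self):
        required = {"A", "Pi", "sd", "n_samples"}
        if not required.issubset(self.points.columns):
            raise ValueError(f"points must have columns {sorted(required)}")
        if np.any(self.points["A"] <= 0):
            raise ValueError("area per lipid must be positive")
        if np.any(self.points["sd"] < 0):
            raise ValueError("sd must be non-negative")
        self.points = self.points.sort_values("A").reset_index(drop=True)

    @property
    def epsilon(self) -> float:
        """Mean absolute error of the binned surface pressure (mean bar size)."""
        return float(self.points["sd"].mean())


# Printed bounds for the sigmoid isotherm fit.
ISOTHERM_BOUNDS = {"b": (0.1, 5.0), "c": (0.5, 1.2), "Pi_rupture": (2.0, 20.0)}


@dataclass
class IsothermFit:
    """Error-function parameterization of a surface-pressure-area isotherm.

    Pi(A) = Pi0 - (Pi_rupture / 2) * (1 + erf(b * (A - c))), with Pi0
    fixed to gamma_water_model - epsilon.
    """

    Pi0: float  # mN/m
    Pi_rupture: float  # mN/m
    b: float  # 1/nm^2
    c: float  # nm^2
    epsilon: float  # mN/m
    gamma_water_model: float  # mN/m
    diagnostics: Optional[dict] = None

    def __post_init__(self):
        lo, hi = ISOTHERM_BOUNDS["b"]
        if not lo < self.b < hi:
            raise ValueError(f"b={self.b} outside ({lo}, {hi})")
        lo, hi = ISOTHERM_BOUNDS["c"]
        if not lo < self.c < hi:
            raise ValueError(f"c={self.c} outside ({lo}, {hi})")
        lo, hi = ISOTHERM_BOUNDS["Pi_rupture"]
        if not lo < self.Pi_rupture < hi:
            raise ValueError(f"Pi_rupture={self.Pi_rupture} outside ({lo}, {hi})")
        if not np.isclose(self.Pi0, self.gamma_water_model - self.epsilon):
            raise ValueError("Pi0 must equal gamma_water_model - epsilon")


@dataclass
class CNTParams:
    """Inputs to the Tolman-corrected nucleation free-energy model."""

    external_pressure: float  # MPa, negative under tension
    n_lipids: int = 30_000
    delta: float = 0.2  # nm, Tolman length
    gamma_water_true: float = 72.0  # mN/m
    gamma_water_model: float = 40.0  # mN/m
    internal_pressure: float = 0.0  # MPa
    temperature: float = DEFAULT_TEMPERATURE_K
    gamma_mode: str = "model"  # which water tension converts Pi -> gamma(r)

    def __post_init__(self):
        if self.n_lipids < 1:
            raise ValueError("n_lipids must be >= 1")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.gamma_mode not in ("model", "corrected"):
            raise ValueError("gamma_mode must be 'model' or 'corrected'")

    @property
    def gamma_water(self) -> float:
        return self.gamma_water_model if self.gamma_mode == "model" else self.gamma_water_true

    @property
    def effective_pressure(self) -> float:
        """Volume-term pressure, MPa: external - internal (< 0 under tension)."""
        return self.external_pressure - self.internal_pressure


@dataclass
class FreeEnergyCurve:
    """Bubble formation free energy g(r) on a radius grid, k_BT units."""

    radii: np.ndarray  # nm, starting at 0
    g: np.ndarray  # k_BT
    params: CNTParams
    fit: IsothermFit

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.radii[0] != 0:
            raise ValueError("radius grid must start at 0")
        if not np.all(np.diff(self.radii) > 0):
            raise ValueError("radii must be strictly increasing")
        if self.g[0] != 0:
            raise ValueError("g(0) must be 0")


@dataclass
class StabilityReport:
    """Extrema of a free-energy landscape and the embolism verdict."""

    r_cavitation_barrier: Optional[float] = None  # nm
    g_cavitation_barrier: Optional[float] = None  # k_BT
    r_metastable: Optional[float] = None  # nm
    g_metastable: Optional[float] = None  # k_BT
    r_embolism_barrier: Optional[float] = None  # nm
    g_embolism_barrier: Optional[float] = None  # k_BT
    embolism_barrier_below_zero: Optional[bool] = None
    monotonic: bool = False

    def __post_init__(self):
        rs = (self.r_cavitation_barrier, self.r_metastable, self.r_embolism_barrier)
        if all(r is not None for r in rs):
            if not (rs[0] < rs[1] < rs[2]):
                raise ValueError(
                    "expected cavitation barrier < metastable radius < embolism barrier"
                )


@dataclass
class RuptureEvent:
    """First sustained crossing of the pore-coverage rupture threshold."""

    time: float  # ps
    pore_fraction_at_event: float
    threshold_used: float

    def __post_init__(self):
        if self.pore_fraction_at_event < self.threshold_used:
            raise ValueError("pore fraction at event must be >= threshold")


@dataclass
class GridSpec:
    """Square occupancy grid used by the pore-area algorithm."""

    M: int  # grid points per side
    spacing: float  # nm
    offset: float  # nm inset from each box wall

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")


@dataclass
class PoreSeries:
    """Pore (exposed water) fraction over time."""

    times: np.ndarray  # ps
    pore_fraction: np.ndarray  # in [0, 1]
    grid: GridSpec
    grid_policy: str = "per_frame"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.pore_fraction = np.asarray(self.pore_fraction, dtype=float)
        if len(self.times) != len(self.pore_fraction):
            raise ValueError("times and pore_fraction must have equal length")
        if np.any((self.pore_fraction < 0) | (self.pore_fraction > 1)):
            raise ValueError("pore fraction must lie in [0, 1]")
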