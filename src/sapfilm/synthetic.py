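"""Synthetic monolayer trajectories, pressure tensors and density profiles.

This module is a phenomenological kinetic emulator, not a molecular
dynamics surrogate.  It reproduces only the *statistical* structure the
downstream estimators assume:

* a square lateral box that expands affinely under tension, with
  head-group positions rattling about liquid-condensed lattice anchors;
* circular pores that nucleate as a Poisson process (rate proportional
  to the applied tension), grow against a constant line-tension-like
  healing rate, and run away exponentially once total coverage crosses
  the rupture threshold;
* a laterally stable "phospholipid" mode whose pore coverage fluctuates
  about an equilibrium fraction while the box stays within 2% of its
  initial width;
* pressure-tensor series whose component anisotropy encodes a target
  surface tension, and error-function slab density profiles with a
  prescribed capillary-wave width.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erf

from .datatypes import (
    GLYCOLIPID,
    LIPID_MODES,
    DensityProfile,
    Frame,
    Isotherm,
    IsothermFit,
    PressureTensorSeries,
    SyntheticTrajectory,
)
from .isotherm import pi_of_area


class PackingError(RuntimeError):
    """Raised when a minimum-separation placement cannot be achieved."""


@dataclass
class PullingParams:
    """Knobs of the synthetic pulling run.

    Rates are free calibration parameters of the emulator (the physical
    system provides no quantitative pore-growth law); the defaults are
    calibrated so that a 25 ns run is laterally stable at -0.5 MPa while
    rupture times decrease strictly over -1.5/-2.5/-3.5 MPa.
    """

    external_pressure: float  # MPa, <= 0
    duration: float = 25.0  # ns
    dt: float = 50.0  # ps per frame
    n_lipids: int = 276
    h_xy0: float = 18.0  # nm
    h_z: float = 60.0  # nm
    expansion_rate_coefficient: float = 2.0  # nm^2 ns^-1 MPa^-1
    pore_nucleation_rate: float = 0.6  # events ns^-1 per unit |MPa|
    pore_growth_rate: float = 1.2  # nm^2 ns^-1 per unit |MPa|
    pore_healing_rate: float = 1.26  # nm^2 ns^-1, constant reseal rate
    runaway_rate: float = 2.0  # ns^-1 exponential growth after threshold
    rupture_threshold: float = 0.10
    mode: str = GLYCOLIPID
    equilibrium_pore_fraction: float = 0.23
    n_equilibrium_pores: int = 10
    jitter_sd: float = 0.08  # nm, thermal rattle about lattice anchors
    seed: int = 0

    def __post_init__(self):
        if self.mode not in LIPID_MODES:
            raise ValueError(f"mode must be one of {LIPID_MODES}")
        if self.external_pressure > 0:
            raise ValueError("pulling runs use external_pressure <= 0 (tension)")
        for name in (
            "expansion_rate_coefficient",
            "pore_nucleation_rate",
            "pore_growth_rate",
            "pore_healing_rate",
            "runaway_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.rupture_threshold < 1:
            raise ValueError("rupture_threshold must be in (0, 1)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def generate_initial_configuration(
    n_lipids: int,
    h_xy: float,
    min_separation: float,
    seed: int,
    max_attempts_per_lipid: int = 200,
    h_z: float = 60.0,
) -> Frame:
    """Semi-random placement with a periodic minimum-separation constraint.

    Rejection sampling: candidates are drawn uniformly and accepted when
    their minimum-image distance to every accepted lipid is at least
    ``min_separation`` (the construction rule that no two particles sit
    closer than the excluded-volume diameter).
    """
    if n_lipids < 1:
        raise ValueError("n_lipids must be >= 1")
    packing = n_lipids * math.pi * (min_separation / 2) ** 2
    if n_lipids > 1 and packing >= 0.7 * h_xy**2:
        raise PackingError(
            f"requested packing fraction {packing / h_xy**2:.2f} exceeds the "
            "0.7 feasibility limit for rejection sampling"
        )
    rng = np.random.default_rng(seed)
    accepted = np.empty((n_lipids, 2))
    n_placed = 0
    attempts = 0
    budget = max_attempts_per_lipid * n_lipids
    while n_placed < n_lipids:
        if attempts >= budget:
            raise PackingError(
                f"placement failed after {attempts} attempts "
                f"({n_placed}/{n_lipids} lipids placed)"
            )
        candidate = rng.uniform(0, h_xy, size=2)
        attempts += 1
        if n_placed:
            d = np.abs(accepted[:n_placed] - candidate)
            d = np.minimum(d, h_xy - d)  # minimum image
            if np.min(np.hypot(d[:, 0], d[:, 1])) < min_separation:
                continue
        accepted[n_placed] = candidate
        n_placed += 1
    return Frame(time=0.0, positions=accepted, h_xy=h_xy, h_z=h_z)


def _lattice_anchors(n_lipids: int, rng: np.random.Generator) -> np.ndarray:
    """Fractional lattice anchors emulating liquid-condensed order.

    Returns (n, 2) fractional coordinates on an n_side x n_side square
    lattice with randomly chosen vacancies when n_side^2 > n_lipids.
    """
    n_side = math.ceil(math.sqrt(n_lipids))
    idx = rng.permutation(n_side * n_side)[:n_lipids]
    ij = np.column_stack(np.divmod(idx, n_side))
    # anchors at lattice nodes i/n_side so an M ~ n_side occupancy grid
    # sees one lipid per cell (liquid-condensed order, low vacancy floor)
    return ij / n_side


def _displace_out_of_pores(positions, pores, h_xy):
    """Push lipids radially out of pore disks (lipid count is conserved)."""
    if not pores:
        return positions
    pos = positions.copy()
    for cx, cy, area in pores:
        if area <= 0:
            continue
        radius = math.sqrt(area / math.pi)
        center = np.array([cx, cy]) * h_xy
        d = pos - center
        d -= h_xy * np.round(d / h_xy)  # minimum image
        dist = np.hypot(d[:, 0], d[:, 1])
        inside = dist < radius
        if not np.any(inside):
            continue
        dist_safe = np.where(dist[inside] < 1e-9, 1e-9, dist[inside])
        scale = radius * 1.05 / dist_safe
        pos[inside] = center + d[inside] * scale[:, None]
    return np.mod(pos, h_xy)


def simulate_pulling(params: PullingParams) -> SyntheticTrajectory:
    """Generate one synthetic pulling trajectory.

    Glycolipid mode: the box area grows at ``expansion_rate_coefficient
    * |p|``, pores nucleate at ``pore_nucleation_rate * |p|`` per ns and
    each grows at net rate ``pore_growth_rate * |p| -
    pore_healing_rate`` (pores reseal below the healing tension); once
    the disk-union coverage reaches ``rupture_threshold`` growth becomes
    exponential and the trajectory is flagged ruptured.

    Phospholipid mode: the box width performs a bounded <0.5% wobble and
    a fixed set of pores fluctuates about ``equilibrium_pore_fraction``.
    """
    if params.duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(params.seed)
    p_abs = abs(params.external_pressure)
    dt_ns = params.dt / 1000.0
    n_frames = int(round(params.duration / dt_ns)) + 1

    anchors = _lattice_anchors(params.n_lipids, rng)
    area0 = params.h_xy0**2
    area = area0
    pores: list[list[float]] = []  # [cx_frac, cy_frac, area_nm2]
    ruptured = False
    rupture_time = None
    frames = []
    geo_fraction = np.zeros(n_frames)
    seed_area = 0.05  # nm^2, nascent pore size

    for i in range(n_frames):
        t_ns = i * dt_ns
        if params.mode == GLYCOLIPID:
            if i > 0:
                area += params.expansion_rate_coefficient * p_abs * dt_ns
                if ruptured:
                    growth = math.exp(params.runaway_rate * dt_ns)
                    for pore in pores:
                        pore[2] *= growth
                else:
                    net = params.pore_growth_rate * p_abs - params.pore_healing_rate
                    for pore in pores:
                        pore[2] += net * dt_ns
                    pores = [p for p in pores if p[2] > 0]
                    n_new = rng.poisson(params.pore_nucleation_rate * p_abs * dt_ns)
                    for _ in range(n_new):
                        cx, cy = rng.uniform(0, 1, size=2)
                        pores.append([cx, cy, seed_area])
        else:  # phospholipid: stationary box, equilibrium pore coverage
            # A snapped-to-grid observer undercounts a disk by roughly a
            # half-spacing rim annulus (rim lipids re-occupy boundary
            # cells), so the emulated disks are inflated by half the
            # implied cell size to make nominal and observed coverage agree.
            cell = math.sqrt(area0) / math.ceil(math.sqrt(params.n_lipids))

            def _inflated(nominal_area: float) -> float:
                return math.pi * (math.sqrt(nominal_area / math.pi) + 0.5 * cell) ** 2

            if i == 0:
                nominal = params.equilibrium_pore_fraction * area / params.n_equilibrium_pores
                target = _inflated(nominal)
                pores = [
                    [rng.uniform(), rng.uniform(), target] for _ in range(params.n_equilibrium_pores)
                ]
            else:
                area = area0 * (1 + 0.004 * math.sin(2 * math.pi * t_ns / params.duration)
                                + rng.normal(0, 5e-4))
                nominal = params.equilibrium_pore_fraction * area / params.n_equilibrium_pores
                target = _inflated(nominal)
                for pore in pores:
                    # mean-reverting fluctuation about the per-pore target
                    pore[2] += 0.5 * (target - pore[2]) * dt_ns + 0.08 * target * math.sqrt(
                        dt_ns
                    ) * rng.normal()
                    pore[2] = max(pore[2], 0.0)

        h_xy = math.sqrt(area)
        total_pore = min(sum(p[2] for p in pores), area)
        geo_fraction[i] = total_pore / area
        if (
            params.mode == GLYCOLIPID
            and not ruptured
            and geo_fraction[i] >= params.rupture_threshold
        ):
            ruptured = True
            rupture_time = t_ns * 1000.0

        positions = anchors * h_xy + rng.normal(0, params.jitter_sd, size=anchors.shape)
        # reflect small negative excursions at the origin instead of
        # wrapping them to the far wall (keeps edge lipids in their cells)
        positions = np.mod(np.abs(positions), h_xy)
        positions = _displace_out_of_pores(positions, [tuple(p) for p in pores], h_xy)
        frames.append(Frame(time=t_ns * 1000.0, positions=positions, h_xy=h_xy, h_z=params.h_z))

    return SyntheticTrajectory(
        frames=frames,
        external_pressure=params.external_pressure,
        lipid_mode=params.mode,
        n_lipids_per_monolayer=params.n_lipids,
        seed=params.seed,
        ruptured=ruptured,
        rupture_time=rupture_time,
        pore_fraction_geometric=geo_fraction,
    )


def generate_pressure_tensor_series(
    gamma_target: float,
    h_z: float,
    n_interfaces: int,
    n_steps: int,
    noise_sd: float,
    seed: int,
    dt: float = 1.0,
    base_pressure: float = 0.1,
) -> PressureTensorSeries:
    """Noisy diagonal pressure components encoding a target tension.

    The component means satisfy ``E[Pz - (Px + Py)/2] = n_interfaces *
    gamma_target / h_z`` (MPa, with gamma in mN/m and h_z in nm), i.e.
    the mechanical estimator recovers ``gamma_target`` in expectation.
    Each component carries i.i.d. Gaussian noise of ``noise_sd``.
    """
    if not np.isfinite(gamma_target):
        raise ValueError("gamma_target must be finite")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if h_z <= 0:
        raise ValueError("h_z must be positive")
    rng = np.random.default_rng(seed)
    delta = n_interfaces * gamma_target / h_z  # MPa
    times = np.arange(n_steps) * dt
    Pz = base_pressure + rng.normal(0, noise_sd, n_steps)
    Px = base_pressure - delta + rng.normal(0, noise_sd, n_steps)
    Py = base_pressure - delta + rng.normal(0, noise_sd, n_steps)
    return PressureTensorSeries(
        times=times, Px=Px, Py=Py, Pz=Pz, h_z=h_z, n_interfaces=n_interfaces
    )


def slab_density(z, z_lo, z_hi, sigma, bulk_density):
    """Error-function slab profile with capillary-wave width ``sigma``."""
    return (
        bulk_density
        / 2.0
        * (erf((z - z_lo) / (sigma * math.sqrt(2))) - erf((z - z_hi) / (sigma * math.sqrt(2))))
    )


def generate_density_profile(
    sigma: float,
    interface_positions: tuple[float, float],
    h_z: float,
    n_slices: int = 300,
    bulk_density: float = 1.0,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> DensityProfile:
    """Slab density profile with erf-broadened interfaces.

    The two interfaces sit at ``interface_positions`` (nm, inside the
    box); the thermally broadened width is ``sigma``.
    """
    if n_slices < 10:
        raise ValueError("n_slices < 10 would make the interface fit ill-posed")
    z_lo, z_hi = sorted(interface_positions)
    if not (0 < z_lo < h_z and 0 < z_hi < h_z):
        raise ValueError("interfaces must lie inside (0, h_z)")
    if not 0 < sigma < h_z:
        raise ValueError("sigma must be positive and well below h_z")
    z = (np.arange(n_slices) + 0.5) * (h_z / n_slices)
    rho = slab_density(z, z_lo, z_hi, sigma, bulk_density)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rho = rho + rng.normal(0, noise_sd, n_slices)
    rho = np.clip(rho, 0.0, None)
    return DensityProfile(z_centers=z, density=rho, h_z=h_z)


def generate_noisy_isotherm(
    fit_true: IsothermFit,
    A_grid,
    sd: float,
    n_reps: int,
    seed: int,
    pressure_label: float = 0.0,
) -> Isotherm:
    """Noisy samples of the sigmoid isotherm, for fit-recovery experiments.

    Each grid area receives ``n_reps`` Gaussian-noise replicates of the
    true curve; the point records their mean, spread and count.
    """
    A_grid = np.asarray(A_grid, dtype=float)
    if A_grid.size == 0:
        raise ValueError("A_grid must not be empty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for A in A_grid:
        true = pi_of_area(fit_true, A)
        samples = true + rng.normal(0, sd, n_reps)
        rows.append(
            {
                "A": A,
                "Pi": float(np.mean(samples)),
                "sd": float(np.std(samples, ddof=1)) if n_reps > 1 else float(sd),
                "n_samples": n_reps,
            }
        )
    return Isotherm(pressure_label=pressure_label, points=pd.DataFrame(rows))
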