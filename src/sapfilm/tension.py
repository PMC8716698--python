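"""Dynamic surface tension: pressure-tensor and capillary-wave estimators.

The mechanical (pressure-tensor) route uses the anisotropy of the
diagonal pressure components in a slab box,

    gamma_PT = (h_z / n) * [Pz - (Px + Py) / 2],

with n the number of interfaces; with h_z in nm and pressures in MPa the
product is already in mN/m.  The capillary-wave route uses the thermal
broadening of the interfacial density profile,

    gamma_CW = k_B T / (2 pi sigma^2) * ln(h_z / l),

where sigma is the erf-fit width of the interface and l a molecular
diameter: the mean of the water van der Waals diameter and the
equivalent head-group disc diameter 2*sqrt(h_xy^2 / (pi * n_lipids)),
which tracks the instantaneous box width as the film is stretched.
The two estimators approach each other as the interface equilibrates,
and their agreement (plus the agreement of the two monolayers' CW
values) justifies using the cumulative PT mean as the film's tension.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .datatypes import DensityProfile, PressureTensorSeries, TensionEstimate
from .units import kbt_joules

#: Water van der Waals diameter, nm.
WATER_VDW_DIAMETER = 0.28


class InterfaceFitError(RuntimeError):
    """Raised when the slab density profile cannot be fitted."""


@dataclass
class CapillaryWaveInputs:
    """Length scales entering the capillary-wave estimator."""

    sigma: float  # nm, interfacial width
    l: float  # nm, molecular diameter
    h_z: float  # nm
    temperature: float = 298.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.l <= 0:
            raise ValueError("l must be positive")
        if self.h_z <= self.l:
            raise ValueError("h_z must exceed the molecular diameter")


def gamma_pressure_tensor(series: PressureTensorSeries) -> TensionEstimate:
    """Per-step and cumulative-mean tension from the pressure tensor."""
    if len(series.times) == 0:
        raise ValueError("empty pressure series")
    if series.n_interfaces == 0:
        raise ValueError("n_interfaces must be nonzero")
    anisotropy = series.Pz - 0.5 * (series.Px + series.Py)  # MPa
    gamma = (series.h_z / series.n_interfaces) * anisotropy  # mN/m
    cumulative = np.cumsum(gamma) / np.arange(1, len(gamma) + 1)
    return TensionEstimate(
        method="pressure_tensor",
        times=series.times,
        gamma=gamma,
        cumulative_gamma=cumulative,
    )


def _double_erf(z, rho0, z_lo, z_hi, sigma):
    from scipy.special import erf

    s = sigma * math.sqrt(2)
    return rho0 / 2.0 * (erf((z - z_lo) / s) - erf((z - z_hi) / s))


def _double_erf_two_sigma(z, rho0, z_lo, z_hi, sigma_lo, sigma_hi):
    from scipy.special import erf

    return rho0 / 2.0 * (
        erf((z - z_lo) / (sigma_lo * math.sqrt(2)))
        - erf((z - z_hi) / (sigma_hi * math.sqrt(2)))
    )


def _initial_guess(profile: DensityProfile):
    z, rho = profile.z_centers, profile.density
    rho0 = float(np.max(rho))
    if rho0 <= 0:
        raise InterfaceFitError("profile has no density")
    half = rho0 / 2.0
    above = rho >= half
    if not above.any() or above.all():
        raise InterfaceFitError("no interface: profile never crosses half maximum")
    idx = np.nonzero(above)[0]
    z_lo, z_hi = z[idx[0]], z[idx[-1]]
    if z_hi - z_lo < 3 * (z[1] - z[0]):
        raise InterfaceFitError("slab too thin to resolve two interfaces")
    # sigma from the 25-75% rise distance of the lower interface
    lower = (z <= 0.5 * (z_lo + z_hi))
    zl, rl = z[lower], rho[lower]
    z25 = np.interp(0.25 * rho0, rl, zl)
    z75 = np.interp(0.75 * rho0, rl, zl)
    sigma0 = max((z75 - z25) / 1.349, (z[1] - z[0]) / 4.0)
    return rho0, float(z_lo), float(z_hi), float(sigma0)


def fit_interface_width(
    profile: DensityProfile,
    independent: bool = False,
    full_output: bool = False,
):
    """Erf-fit width sigma of a two-interface slab density profile.

    By default the two interfaces share one width; with ``independent``
    each interface gets its own and the mean is returned.  With
    ``full_output`` a dict with the fitted parameters, per-interface
    widths and residual norm is returned alongside sigma.
    """
    rho0, z_lo, z_hi, sigma0 = _initial_guess(profile)
    z, rho = profile.z_centers, profile.density
    try:
        if independent:
            popt, _ = curve_fit(
                _double_erf_two_sigma,
                z,
                rho,
                p0=[rho0, z_lo, z_hi, sigma0, sigma0],
                bounds=([0, 0, 0, 1e-4, 1e-4], [np.inf, profile.h_z, profile.h_z, profile.h_z, profile.h_z]),
                maxfev=20_000,
            )
            sigma_lo, sigma_hi = popt[3], popt[4]
            sigma = 0.5 * (sigma_lo + sigma_hi)
        else:
            popt, _ = curve_fit(
                _double_erf,
                z,
                rho,
                p0=[rho0, z_lo, z_hi, sigma0],
                bounds=([0, 0, 0, 1e-4], [np.inf, profile.h_z, profile.h_z, profile.h_z]),
                maxfev=20_000,
            )
            sigma_lo = sigma_hi = sigma = popt[3]
    except RuntimeError as exc:
        residual = "fit did not converge"
        raise InterfaceFitError(f"interface fit failed: {residual}: {exc}") from exc
    model = (
        _double_erf_two_sigma(z, *popt) if independent else _double_erf(z, *popt)
    )
    resid = float(np.sqrt(np.mean((rho - model) ** 2)))
    if full_output:
        return float(sigma), {
            "sigma_lo": float(sigma_lo),
            "sigma_hi": float(sigma_hi),
            "rho0": float(popt[0]),
            "z_lo": float(popt[1]),
            "z_hi": float(popt[2]),
            "rmse": resid,
        }
    return float(sigma)


def molecular_diameter(h_xy: float, n_lipids: int, water_vdw_diameter: float = WATER_VDW_DIAMETER) -> float:
    """Mean of the water vdW diameter and the head-group disc diameter.

    The head-group diameter is that of a disc carrying the per-lipid
    area: d = 2 * sqrt(h_xy^2 / (pi * n_lipids)); it changes with the
    instantaneous box width.
    """
    if n_lipids < 1:
        raise ValueError("n_lipids must be >= 1")
    if h_xy <= 0:
        raise ValueError("h_xy must be positive")
    d = 2.0 * math.sqrt(h_xy**2 / (math.pi * n_lipids))
    return 0.5 * (water_vdw_diameter + d)


def gamma_capillary_wave(inputs: CapillaryWaveInputs) -> float:
    """Capillary-wave tension in mN/m from width sigma and diameter l."""
    kbt = kbt_joules(inputs.temperature)
    sigma_m = inputs.sigma * 1e-9
    gamma_n_per_m = kbt / (2 * math.pi * sigma_m**2) * math.log(inputs.h_z / inputs.l)
    return gamma_n_per_m * 1e3


def chunked_cw_series(
    times,
    profiles: list[DensityProfile],
    h_xy,
    n_lipids: int,
    chunk_length: float = 500.0,
    temperature: float = 298.0,
    water_vdw_diameter: float = WATER_VDW_DIAMETER,
) -> TensionEstimate:
    """Capillary-wave tension in time chunks from per-frame density profiles.

    Within each chunk the density profiles are accumulated and fitted
    once for the headline sigma; the two interfaces are also fitted
    independently, frame by frame, to give per-interface estimates and a
    within-chunk spread.  The molecular diameter uses the chunk-mean box
    width.  Chunks with fewer than two frames are skipped with a warning.
    """
    times = np.asarray(times, dtype=float)
    h_xy = np.broadcast_to(np.asarray(h_xy, dtype=float), times.shape)
    if len(times) != len(profiles):
        raise ValueError("times and profiles must have equal length")
    if len(times) == 0:
        raise ValueError("no frames")
    span = times[-1] - times[0]
    if span + 1e-9 < chunk_length:
        raise ValueError("trajectory shorter than one chunk")
    edges = np.arange(times[0], times[-1] + chunk_length, chunk_length)
    chunk_times, gammas, tops, bottoms, sds = [], [], [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = np.nonzero((times >= lo) & (times < hi))[0]
        if len(sel) < 2:
            warnings.warn(f"chunk [{lo}, {hi}) ps has <2 frames; skipped", stacklevel=2)
            continue
        ref = profiles[sel[0]]
        mean_density = np.mean([profiles[i].density for i in sel], axis=0)
        mean_profile = DensityProfile(
            z_centers=ref.z_centers, density=mean_density, h_z=ref.h_z
        )
        l = molecular_diameter(float(np.mean(h_xy[sel])), n_lipids, water_vdw_diameter)
        sigma = fit_interface_width(mean_profile)
        gamma = gamma_capillary_wave(
            CapillaryWaveInputs(sigma=sigma, l=l, h_z=ref.h_z, temperature=temperature)
        )
        per_top, per_bottom = [], []
        for i in sel:
            try:
                _, info = fit_interface_width(profiles[i], independent=True, full_output=True)
            except InterfaceFitError:
                continue
            for sig, store in ((info["sigma_lo"], per_bottom), (info["sigma_hi"], per_top)):
                store.append(
                    gamma_capillary_wave(
                        CapillaryWaveInputs(
                            sigma=sig, l=l, h_z=profiles[i].h_z, temperature=temperature
                        )
                    )
                )
        both = per_top + per_bottom
        chunk_times.append(0.5 * (lo + hi))
        gammas.append(gamma)
        tops.append(float(np.mean(per_top)) if per_top else np.nan)
        bottoms.append(float(np.mean(per_bottom)) if per_bottom else np.nan)
        sds.append(float(np.std(both, ddof=1)) if len(both) > 1 else np.nan)
    if not gammas:
        raise ValueError("no chunk had enough frames")
    return TensionEstimate(
        method="capillary_wave",
        times=np.array(chunk_times),
        gamma=np.array(gammas),
        chunk_length=chunk_length,
        gamma_top=np.array(tops),
        gamma_bottom=np.array(bottoms),
        gamma_sd=np.array(sds),
    )


def convergence_report(
    pt: TensionEstimate,
    cw: TensionEstimate,
    tolerance: float = 2.0,
) -> dict:
    """Compare cumulative PT tension with chunked CW tension.

    Reports the per-chunk absolute difference, the first chunk time at
    which the two estimators agree within ``tolerance`` (mN/m), and
    whether the two monolayers' CW estimates ever differ by more than
    one within-chunk standard deviation (the rule for accepting the PT
    value as the mean film behavior).
    """
    if pt.method != "pressure_tensor" or cw.method != "capillary_wave":
        raise ValueError("pass one pressure_tensor and one capillary_wave estimate")
    lo = max(pt.times.min(), cw.times.min())
    hi = min(pt.times.max(), cw.times.max())
    if lo > hi:
        raise ValueError("estimates cover disjoint time ranges")
    mask = (cw.times >= lo) & (cw.times <= hi)
    t = cw.times[mask]
    pt_interp = np.interp(t, pt.times, pt.cumulative_gamma)
    diff = np.abs(pt_interp - cw.gamma[mask])
    within = diff <= tolerance
    first = float(t[np.argmax(within)]) if within.any() else None
    violations = []
    if cw.gamma_top is not None and cw.gamma_bottom is not None and cw.gamma_sd is not None:
        gap = np.abs(cw.gamma_top - cw.gamma_bottom)
        with np.errstate(invalid="ignore"):
            bad = np.isfinite(gap) & np.isfinite(cw.gamma_sd) & (gap > cw.gamma_sd)
        violations = [float(tt) for tt, flag in zip(cw.times, bad) if flag]
    return {
        "times": t,
        "abs_difference": diff,
        "tolerance": tolerance,
        "first_agreement_time": first,
        "top_bottom_rule_violations": violations,
        "top_bottom_rule_ok": len(violations) == 0,
    }
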