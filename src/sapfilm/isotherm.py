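"""Surface-pressure-area isotherms and their sigmoid parameterization.

Surface pressure is the film's reduction of the bare-water tension,

    Pi(A) = gamma_water - gamma_interface(A),

and a rupturing monolayer is parameterized by the error-function step

    Pi(A) = Pi0 - (Pi_rupture / 2) * (1 + erf(b * (A - c))),

which plateaus at Pi0 for a compact film (small area per lipid A) and
falls to Pi0 - Pi_rupture once the film has ruptured.  Pi0 is not fitted:
it is pinned to gamma_water - epsilon, where epsilon is the mean error
bar of the binned data.  The abscissa is area per lipid (nm^2), which
grows during pulling so that Pi decreases toward zero as the interface
expands; the reciprocal lipid number density is emitted alongside for
cross-checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import erf

from .datatypes import ISOTHERM_BOUNDS, Isotherm, IsothermFit, SyntheticTrajectory


class FitError(RuntimeError):
    """Raised when a bounded isotherm fit fails or pins at its bounds."""


def surface_pressure(gamma_interface, gamma_water):
    """Pi = gamma_water - gamma_interface (mN/m)."""
    return gamma_water - np.asarray(gamma_interface, dtype=float) * 1.0


def gamma_from_pressure(Pi, gamma_water):
    """Inverse conversion: gamma_interface = gamma_water - Pi."""
    return gamma_water - np.asarray(Pi, dtype=float) * 1.0


def pi_of_area(fit: IsothermFit, A):
    """Evaluate the sigmoid isotherm at area per lipid ``A`` (nm^2)."""
    A = np.asarray(A, dtype=float)
    return fit.Pi0 - fit.Pi_rupture / 2.0 * (1.0 + erf(fit.b * (A - fit.c)))


def area_per_lipid_series(traj: SyntheticTrajectory) -> pd.DataFrame:
    """Per-frame area per lipid and its reciprocal number density.

    Columns: time (ps), A (nm^2 per lipid), density (lipids nm^-2).
    """
    times = traj.times
    A = np.array([f.h_xy**2 for f in traj.frames]) / traj.n_lipids_per_monolayer
    return pd.DataFrame({"time": times, "A": A, "density": 1.0 / A})


def bin_isotherm(
    Pi_series: pd.DataFrame,
    A_series: pd.DataFrame,
    n_bins: int,
    post_rupture_cutoff: float | None = None,
    pressure_label: float = 0.0,
) -> Isotherm:
    """Bin (Pi, A) samples sharing a time base into an isotherm.

    ``Pi_series`` has columns (time, Pi); ``A_series`` has (time, A).
    Samples at or after ``post_rupture_cutoff`` (ps) are excluded -- the
    film past rupture no longer reports a meaningful film pressure.
    Bins are equal-width in A; each keeps the mean, the one-standard-
    deviation bar and the sample count.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    merged = pd.merge(Pi_series[["time", "Pi"]], A_series[["time", "A"]], on="time")
    if len(merged) != len(Pi_series) or len(merged) != len(A_series):
        raise ValueError("Pi and A series must share a common time base")
    if post_rupture_cutoff is not None:
        merged = merged[merged["time"] < post_rupture_cutoff]
    if merged.empty:
        raise ValueError("no samples left to bin (cutoff before all samples?)")
    edges = np.linspace(merged["A"].min(), merged["A"].max(), n_bins + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)  # keep the right-most sample
    idx = np.digitize(merged["A"], edges) - 1
    rows = []
    for k in range(n_bins):
        sel = merged[idx == k]
        if sel.empty:
            continue
        sd = float(sel["Pi"].std(ddof=1)) if len(sel) > 1 else 0.0
        rows.append(
            {
                "A": float(sel["A"].mean()),
                "Pi": float(sel["Pi"].mean()),
                "sd": sd,
                "n_samples": int(len(sel)),
            }
        )
    if len(rows) < 3:
        raise ValueError(f"only {len(rows)} non-empty bins; need >= 3")
    return Isotherm(pressure_label=pressure_label, points=pd.DataFrame(rows))


def fit_isotherm(
    iso: Isotherm,
    gamma_water_model: float,
    weighted: bool = True,
    epsilon: float | None = None,
) -> IsothermFit:
    """Bounded nonlinear least-squares fit of the sigmoid isotherm.

    Pi0 is fixed to ``gamma_water_model - epsilon`` (epsilon defaults to
    the isotherm's mean bar size); only (b, c, Pi_rupture) are free,
    inside the bounds 0.1 < b < 5, 0.5 < c < 1.2 nm^2 and
    2 < Pi_rupture < 20 mN/m.  Points are weighted by 1/sd when every
    bar is positive and ``weighted`` is set.

    Raises
    ------
    FitError
        On non-convergence, or when more than one parameter is pinned at
        a bound (the signature of mis-scaled data: the sigmoid cannot
        describe it inside the physical box).
    """
    pts = iso.points
    if len(pts) < 4:
        raise FitError("need at least 4 points spanning the transition")
    eps = iso.epsilon if epsilon is None else float(epsilon)
    Pi0 = gamma_water_model - eps

    def model(A, b, c, Pi_rupture):
        return Pi0 - Pi_rupture / 2.0 * (1.0 + erf(b * (A - c)))

    lo = [ISOTHERM_BOUNDS["b"][0], ISOTHERM_BOUNDS["c"][0], ISOTHERM_BOUNDS["Pi_rupture"][0]]
    hi = [ISOTHERM_BOUNDS["b"][1], ISOTHERM_BOUNDS["c"][1], ISOTHERM_BOUNDS["Pi_rupture"][1]]

    # initialization: c where Pi first drops below Pi0 minus half the
    # bound-midpoint step; b at 1; Pi_rupture at the bound midpoint
    pi_mid = 0.5 * (lo[2] + hi[2])
    below = pts[pts["Pi"] < Pi0 - pi_mid / 2.0]
    c0 = float(below["A"].iloc[0]) if not below.empty else float(pts["A"].median())
    c0 = min(max(c0, lo[1] + 1e-3), hi[1] - 1e-3)
    p0 = [1.0, c0, pi_mid]

    sigma = None
    if weighted and (pts["sd"] > 0).all():
        sigma = pts["sd"].to_numpy()
    try:
        popt, pcov = curve_fit(
            model,
            pts["A"].to_numpy(),
            pts["Pi"].to_numpy(),
            p0=p0,
            bounds=(lo, hi),
            sigma=sigma,
            maxfev=10_000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        raise FitError(f"isotherm fit did not converge: {exc}") from exc

    pinned = [
        name
        for name, value, l, h in zip(("b", "c", "Pi_rupture"), popt, lo, hi)
        if value - l < 1e-3 * (h - l) or h - value < 1e-3 * (h - l)
    ]
    if len(pinned) > 1:
        raise FitError(
            f"fit pinned at bounds for {pinned}; the data do not span a "
            "sigmoid transition inside the physical bounds"
        )
    residuals = pts["Pi"].to_numpy() - model(pts["A"].to_numpy(), *popt)
    b, c, pi_rupture = popt
    # nudge a single pinned parameter strictly inside its open bound
    b = min(max(b, np.nextafter(lo[0], np.inf)), np.nextafter(hi[0], -np.inf))
    c = min(max(c, np.nextafter(lo[1], np.inf)), np.nextafter(hi[1], -np.inf))
    pi_rupture = min(max(pi_rupture, np.nextafter(lo[2], np.inf)), np.nextafter(hi[2], -np.inf))
    return IsothermFit(
        Pi0=Pi0,
        Pi_rupture=float(pi_rupture),
        b=float(b),
        c=float(c),
        epsilon=eps,
        gamma_water_model=gamma_water_model,
        diagnostics={
            "rmse": float(np.sqrt(np.mean(residuals**2))),
            "pinned": pinned,
            "covariance": pcov.tolist(),
            "weighted": sigma is not None,
        },
    )


def corrected_gamma(fit_or_Pi, gamma_water_true: float, A_domain=None):
    """Corrected interfacial tension gamma = gamma_water_true - Pi.

    Given an :class:`IsothermFit` plus an area domain, reports the
    attained [min, max] gamma range over that domain; given raw Pi
    values, converts them directly.

    Returns
    -------
    dict with keys ``gamma`` (array or None), ``gamma_min``, ``gamma_max``.
    """
    if isinstance(fit_or_Pi, IsothermFit):
        if A_domain is None:
            raise ValueError("an area domain is required with an IsothermFit")
        Pi = pi_of_area(fit_or_Pi, np.asarray(A_domain, dtype=float))
    else:
        Pi = np.asarray(fit_or_Pi, dtype=float)
    gamma = gamma_from_pressure(Pi, gamma_water_true)
    return {
        "gamma": gamma,
        "gamma_min": float(np.min(gamma)),
        "gamma_max": float(np.max(gamma)),
    }
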