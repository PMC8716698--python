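"""Configuration handling and the staged analysis pipeline.

The pipeline strings the library stages together on synthetic data:

    simulate -> pore -> tension -> isotherm -> cnt -> laplace

Each stage reads its inputs from the in-memory state left by earlier
stages (or fails naming the missing artifact), writes versioned text
artifacts into the output directory, and the fully resolved
configuration is written next to the outputs.  No artifact embeds a
timestamp, so identical configurations reproduce byte-identical files.
"""

from __future__ import annotations

import copy
import json
import logging
import math
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cnt import analyze_landscape, free_energy_curve, laplace_sweep, representative_fit
from .datatypes import CNTParams, IsothermFit
from .fileio import write_csv_with_header, write_gro_frames, write_pore_series_xvg
from .isotherm import fit_isotherm
from .pore import detect_rupture, pore_area_series, pore_series_frame
from .synthetic import (
    PullingParams,
    generate_density_profile,
    generate_noisy_isotherm,
    simulate_pulling,
)
from .tension import (
    chunked_cw_series,
    convergence_report,
    gamma_pressure_tensor,
    molecular_diameter,
)
from .units import kbt_joules

logger = logging.getLogger("sapfilm")

STAGES = ("simulate", "pore", "tension", "isotherm", "cnt", "laplace")


class PipelineError(RuntimeError):
    """Raised for unsatisfiable stage dependencies or bad configuration."""


#: The study-defaults profile: the standard constants of the slab setup.
DEFAULT_CONFIG: dict = {
    "seed": 1,
    "simulate": {
        "pressures": [-0.5, -1.5, -2.5, -3.5],
        "phospholipid_pressure": -5.5,
        "duration_ns": 25.0,
        "phospholipid_duration_ns": 22.5,
        "dt_ps": 50.0,
        "n_lipids_glycolipid": 276,
        "n_lipids_phospholipid": 280,
        "h_xy0_nm": 18.0,
        "h_z_glycolipid_nm": 60.0,
        "h_z_phospholipid_nm": 45.0,
        "expansion_rate_coefficient": 2.0,
        "pore_nucleation_rate": 0.6,
        "pore_growth_rate": 1.2,
        "pore_healing_rate": 1.26,
        "equilibrium_pore_fraction": 0.23,
        "write_gro": True,
    },
    "pore": {
        "grid_policy": "per_frame",
        "offset_fraction": 0.01,
        "rupture_threshold": 0.10,
        "min_consecutive": 3,
    },
    "tension": {
        "gamma_water_model_mNm": 40.0,
        "gamma_target_mNm": 40.0,
        "n_steps": 20000,
        "dt_ps": 1.0,
        "noise_sd_MPa": 1.0,
        "chunk_length_ps": 500.0,
        "n_slices": 300,
        "cw_duration_ps": 5000.0,
        "cw_dt_ps": 100.0,
        "profile_noise_sd": 0.01,
        "convergence_tolerance_mNm": 2.0,
    },
    "isotherm": {
        "truth_b": 1.5,
        "truth_c": 0.9,
        # the generating plateau is gamma_water - truth_epsilon; keeping
        # truth_epsilon equal to the noise amplitude makes the fit's
        # data-estimated Pi0 consistent with the generating curve
        "truth_epsilon": 1.5,
        "truth_Pi_rupture": [8.0, 11.0, 14.0, 17.0],
        "A_min": 0.55,
        "A_max": 1.6,
        "n_areas": 40,
        "noise_sd_mNm": 1.5,
        "n_reps": 20,
        "weighted": True,
    },
    "cnt": {
        "n_lipids": 30000,
        "delta_nm": 0.2,
        "gamma_water_true_mNm": 72.0,
        "gamma_water_model_mNm": 40.0,
        "gamma_mode": "model",
        "internal_pressure_MPa": 0.0,
        "temperature_K": 298.0,
        "use_representative_fits": True,
        "r_max_nm": 120.0,
        "n_points": 4801,
    },
}


def _check_keys(config: dict, reference: dict, path: str = ""):
    for key, value in config.items():
        if key not in reference:
            raise PipelineError(f"unknown configuration key {path + key!r}")
        if isinstance(reference[key], dict):
            if not isinstance(value, dict):
                raise PipelineError(f"configuration key {path + key!r} must be a mapping")
            _check_keys(value, reference[key], path + key + ".")


def resolve_config(overrides: dict | None = None) -> dict:
    """Default configuration updated with ``overrides`` (strict keys)."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if overrides:
        _check_keys(overrides, DEFAULT_CONFIG)
        def _merge(base, over):
            for k, v in over.items():
                if isinstance(v, dict):
                    _merge(base[k], v)
                else:
                    base[k] = v
        _merge(config, overrides)
    return config


def load_config(path) -> dict:
    """Resolve a YAML configuration file against the defaults."""
    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    return resolve_config(overrides)


def sigma_for_gamma(gamma: float, l: float, h_z: float, temperature: float = 298.0) -> float:
    """Interface width whose capillary-wave tension equals ``gamma`` (mN/m)."""
    kbt = kbt_joules(temperature)
    sigma_m = math.sqrt(kbt / (2 * math.pi * gamma * 1e-3) * math.log(h_z / l))
    return sigma_m * 1e9


def _write_json(path: Path, payload: dict):
    payload = dict(payload)
    payload["sapfilm_version"] = __version__
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# --- stages ----------------------------------------------------------------

def _stage_simulate(state, config, outdir):
    sim = config["simulate"]
    trajectories = {}
    for k, p in enumerate(sim["pressures"]):
        params = PullingParams(
            external_pressure=p,
            duration=sim["duration_ns"],
            dt=sim["dt_ps"],
            n_lipids=sim["n_lipids_glycolipid"],
            h_xy0=sim["h_xy0_nm"],
            h_z=sim["h_z_glycolipid_nm"],
            expansion_rate_coefficient=sim["expansion_rate_coefficient"],
            pore_nucleation_rate=sim["pore_nucleation_rate"],
            pore_growth_rate=sim["pore_growth_rate"],
            pore_healing_rate=sim["pore_healing_rate"],
            mode="glycolipid",
            seed=config["seed"] * 1000 + k,
        )
        trajectories[p] = simulate_pulling(params)
        if sim["write_gro"]:
            write_gro_frames(trajectories[p], outdir / f"trajectory_p{p}.gro")
    pe_params = PullingParams(
        external_pressure=sim["phospholipid_pressure"],
        duration=sim["phospholipid_duration_ns"],
        dt=sim["dt_ps"],
        n_lipids=sim["n_lipids_phospholipid"],
        h_xy0=sim["h_xy0_nm"],
        h_z=sim["h_z_phospholipid_nm"],
        mode="phospholipid",
        equilibrium_pore_fraction=sim["equilibrium_pore_fraction"],
        seed=config["seed"] * 1000 + 99,
    )
    state["trajectories"] = trajectories
    state["pe_trajectory"] = simulate_pulling(pe_params)
    if sim["write_gro"]:
        write_gro_frames(state["pe_trajectory"], outdir / "trajectory_phospholipid.gro")


def _stage_pore(state, config, outdir):
    if "trajectories" not in state:
        raise PipelineError("stage 'pore' missing artifact 'trajectories' (run simulate)")
    pconf = config["pore"]
    events = {}
    state["pore_series"] = {}
    for p, traj in list(state["trajectories"].items()) + [("phospholipid", state["pe_trajectory"])]:
        series = pore_area_series(
            traj,
            grid_policy=pconf["grid_policy"],
            offset_fraction=pconf["offset_fraction"],
        )
        state["pore_series"][p] = series
        label = f"p{p}" if p != "phospholipid" else "phospholipid"
        write_pore_series_xvg(outdir / f"pore_area_{label}.xvg", series)
        write_csv_with_header(
            outdir / f"pore_area_{label}.csv",
            pore_series_frame(series),
            params={"grid_policy": pconf["grid_policy"], "offset_fraction": pconf["offset_fraction"]},
        )
        if p == "phospholipid":
            # equilibrium coverage, not runaway: report stability stats
            widths = [f.h_xy for f in traj.frames]
            state["pe_stats"] = {
                "mean_pore_fraction": float(series.pore_fraction.mean()),
                "lateral_growth_percent": float(100.0 * (max(widths) / widths[0] - 1.0)),
            }
            continue
        event = detect_rupture(
            series, threshold=pconf["rupture_threshold"], min_consecutive=pconf["min_consecutive"]
        )
        events[str(p)] = (
            None
            if event is None
            else {
                "time_ps": event.time,
                "pore_fraction": event.pore_fraction_at_event,
                "threshold": event.threshold_used,
            }
        )
    state["rupture_events"] = events
    _write_json(outdir / "rupture_events.json", {"events": events, "phospholipid": state["pe_stats"]})


def _stage_tension(state, config, outdir):
    tconf = config["tension"]
    sim = config["simulate"]
    h_z = sim["h_z_glycolipid_nm"]
    gamma = tconf["gamma_target_mNm"]
    seed = config["seed"] * 1000 + 7
    from .synthetic import generate_pressure_tensor_series

    series = generate_pressure_tensor_series(
        gamma_target=gamma,
        h_z=h_z,
        n_interfaces=2,
        n_steps=tconf["n_steps"],
        noise_sd=tconf["noise_sd_MPa"],
        seed=seed,
        dt=tconf["dt_ps"],
    )
    pt = gamma_pressure_tensor(series)
    # capillary-wave input: stationary slab whose erf width encodes the
    # same tension, so the two estimators should converge
    n_lipids = sim["n_lipids_glycolipid"]
    h_xy = sim["h_xy0_nm"]
    l = molecular_diameter(h_xy, n_lipids)
    sigma = sigma_for_gamma(gamma, l, h_z)
    rng_seed = config["seed"] * 1000 + 8
    times = np.arange(0.0, tconf["cw_duration_ps"], tconf["cw_dt_ps"])
    profiles = [
        generate_density_profile(
            sigma=sigma,
            interface_positions=(h_z / 3.0, 2.0 * h_z / 3.0),
            h_z=h_z,
            n_slices=tconf["n_slices"],
            seed=rng_seed + i,
            noise_sd=tconf["profile_noise_sd"],
        )
        for i, _ in enumerate(times)
    ]
    cw = chunked_cw_series(
        times, profiles, h_xy, n_lipids, chunk_length=tconf["chunk_length_ps"]
    )
    report = convergence_report(pt, cw, tolerance=tconf["convergence_tolerance_mNm"])
    state["tension_pt"] = pt
    state["tension_cw"] = cw
    write_csv_with_header(
        outdir / "tension_pressure_tensor.csv",
        pd.DataFrame(
            {
                "time_ps": pt.times,
                "gamma_mN_per_m": pt.gamma,
                "cumulative_gamma_mN_per_m": pt.cumulative_gamma,
            }
        ),
        params={"method": "pressure_tensor", "h_z_nm": h_z, "n_interfaces": 2},
    )
    write_csv_with_header(
        outdir / "tension_capillary_wave.csv",
        pd.DataFrame(
            {
                "time_ps": cw.times,
                "gamma_mN_per_m": cw.gamma,
                "gamma_top_mN_per_m": cw.gamma_top,
                "gamma_bottom_mN_per_m": cw.gamma_bottom,
                "gamma_sd_mN_per_m": cw.gamma_sd,
            }
        ),
        params={"method": "capillary_wave", "chunk_length_ps": cw.chunk_length},
    )
    _write_json(
        outdir / "tension_convergence.json",
        {
            "first_agreement_time_ps": report["first_agreement_time"],
            "tolerance_mN_per_m": report["tolerance"],
            "top_bottom_rule_ok": report["top_bottom_rule_ok"],
        },
    )


def _stage_isotherm(state, config, outdir):
    iconf = config["isotherm"]
    sim = config["simulate"]
    gamma_water = config["tension"]["gamma_water_model_mNm"]
    A_grid = np.linspace(iconf["A_min"], iconf["A_max"], iconf["n_areas"])
    fits = {}
    for k, (p, pi_rupture) in enumerate(zip(sim["pressures"], iconf["truth_Pi_rupture"])):
        truth = IsothermFit(
            Pi0=gamma_water - iconf["truth_epsilon"],
            Pi_rupture=pi_rupture,
            b=iconf["truth_b"],
            c=iconf["truth_c"],
            epsilon=iconf["truth_epsilon"],
            gamma_water_model=gamma_water,
        )
        iso = generate_noisy_isotherm(
            truth,
            A_grid,
            sd=iconf["noise_sd_mNm"],
            n_reps=iconf["n_reps"],
            seed=config["seed"] * 1000 + 50 + k,
            pressure_label=p,
        )
        fit = fit_isotherm(iso, gamma_water, weighted=iconf["weighted"])
        fits[p] = fit
        write_csv_with_header(
            outdir / f"isotherm_p{p}.csv", iso.points, params={"pressure_MPa": p}
        )
        payload = asdict(fit)
        payload["pressure_MPa"] = p
        payload["truth"] = {
            "b": truth.b, "c": truth.c, "Pi_rupture": truth.Pi_rupture,
        }
        _write_json(outdir / f"isotherm_fit_p{p}.json", payload)
    state["isotherm_fits"] = fits


def _stage_cnt(state, config, outdir):
    cconf = config["cnt"]
    pressures = config["simulate"]["pressures"]
    if cconf["use_representative_fits"]:
        fits = {p: representative_fit(p, cconf["gamma_water_model_mNm"]) for p in pressures}
    else:
        if "isotherm_fits" not in state:
            raise PipelineError("stage 'cnt' missing artifact 'isotherm_fits' (run isotherm)")
        fits = state["isotherm_fits"]
    curves = {}
    table = []
    for p in pressures:
        params = CNTParams(
            external_pressure=p,
            n_lipids=cconf["n_lipids"],
            delta=cconf["delta_nm"],
            gamma_water_true=cconf["gamma_water_true_mNm"],
            gamma_water_model=cconf["gamma_water_model_mNm"],
            internal_pressure=cconf["internal_pressure_MPa"],
            temperature=cconf["temperature_K"],
            gamma_mode=cconf["gamma_mode"],
        )
        curve = free_energy_curve(
            params, fits[p], r_max=cconf["r_max_nm"], n_points=cconf["n_points"]
        )
        curves[p] = curve
        report = analyze_landscape(curve)
        table.append({"p_external_MPa": p, **{k: v for k, v in asdict(report).items()}})
        write_csv_with_header(
            outdir / f"free_energy_p{p}.csv",
            pd.DataFrame(
                {
                    "r_nm": curve.radii,
                    "g_kBT": curve.g,
                    "g_1e4_kBT": curve.g / 1e4,
                }
            ),
            params={"pressure_MPa": p, "n_lipids": cconf["n_lipids"], "delta_nm": cconf["delta_nm"],
                    "gamma_mode": cconf["gamma_mode"]},
        )
    state["cnt_curves"] = curves
    state["cnt_fits"] = fits
    state["stability_table"] = table
    _write_json(outdir / "stability_table.json", {"landscapes": table})


def _stage_laplace(state, config, outdir):
    if "cnt_fits" not in state:
        raise PipelineError("stage 'laplace' missing artifact 'cnt_fits' (run cnt)")
    cconf = config["cnt"]
    pressures = config["simulate"]["pressures"]
    params = CNTParams(
        external_pressure=pressures[0],
        n_lipids=cconf["n_lipids"],
        delta=cconf["delta_nm"],
        gamma_water_true=cconf["gamma_water_true_mNm"],
        gamma_water_model=cconf["gamma_water_model_mNm"],
        internal_pressure=cconf["internal_pressure_MPa"],
        temperature=cconf["temperature_K"],
        gamma_mode=cconf["gamma_mode"],
    )
    table = laplace_sweep(
        state["cnt_fits"], params, pressures, r_max=cconf["r_max_nm"], n_points=cconf["n_points"]
    )
    state["laplace_table"] = table
    write_csv_with_header(
        outdir / "laplace_sweep.csv",
        table.rename(
            columns={
                "p_external": "p_external_MPa",
                "r_metastable": "r_metastable_nm",
                "gamma_at_metastable": "gamma_mN_per_m",
                "p_laplace": "p_laplace_MPa",
            }
        ),
        params={"gamma_scale": "corrected (experimental water)"},
    )


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "pore": _stage_pore,
    "tension": _stage_tension,
    "isotherm": _stage_isotherm,
    "cnt": _stage_cnt,
    "laplace": _stage_laplace,
}


def run_pipeline(config: dict | None = None, stages=STAGES, outdir="sapfilm_out") -> dict:
    """Execute the requested stages in canonical order.

    Returns the in-memory state (trajectories, estimates, fits, curves,
    tables); artifacts and the resolved configuration land in ``outdir``.
    """
    config = resolve_config(None) if config is None else config
    _check_keys(config, DEFAULT_CONFIG)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config_resolved.yaml").write_text(
        yaml.safe_dump({"sapfilm_version": __version__, **config}, sort_keys=True)
    )
    state: dict = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        _STAGE_FUNCS[stage](state, config, outdir)
        logger.info("stage %s finished in %.2f s", stage, time.perf_counter() - t0)
    return state
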