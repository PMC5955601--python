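"""End-to-end experiments: frequency sweeps, resonance characterization and
config-driven runs with CSV/JSON outputs.

Named locations follow the conventions of the analysis: ``soma`` is the soma
compartment (or, on soma-free cable fixtures, the compartment closest to the
junction/root), ``apical_end`` / ``basal_end`` the compartment of maximal
path distance in that region (ties broken by lowest index), and
``region@distance`` selects the compartment of a region nearest a path
distance in um.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .membrane import (
    DistributionSpec,
    ModelInstance,
    QAChannel,
    add_shunt,
    add_uniform_conductance,
    boltzmann_channel,
    build_model,
    distribute_conductance,
    freeze_channel,
    set_uniform_rest,
)
from .morphology import FieldAxis, build_compartments, compute_field_axis, read_swc, scale_membrane_area
from .resonance import ResonanceSummary, default_frequency_grid, detect_resonance
from .solver import SensitivityProfile, StimulusSpec, solve_frequency
from . import synthetic

log = logging.getLogger("fieldpol")


def resolve_location(graph, name: str) -> int:
    """Resolve a named location to a compartment index."""
    region = graph.region.astype(str)
    name = str(name)
    if name == "soma":
        soma = np.nonzero(region == "soma")[0]
        if len(soma):
            return int(soma[0])
        return int(np.argmin(graph.path_dist_um))
    if name.endswith("_end"):
        reg = name[: -len("_end")]
        idx = np.nonzero(region == reg)[0]
        if len(idx):
            d = graph.path_dist_um[idx]
            return int(idx[np.argmax(d)])
    if "@" in name:
        reg, _, dist = name.partition("@")
        idx = np.nonzero(region == reg)[0]
        if len(idx):
            return int(idx[np.argmin(np.abs(graph.path_dist_um[idx] - float(dist)))])
    try:
        i = int(name)
        if 0 <= i < graph.n:
            return i
    except ValueError:
        pass
    available = sorted(set(region)) + ["soma", "<region>_end", "<region>@<dist_um>", "<index>"]
    raise KeyError(f"unknown location {name!r}; available: {available}")


def frequency_sweep(
    model: ModelInstance,
    axis: FieldAxis,
    frequencies_hz,
    locations: dict[str, int] | list[str],
    e0: float = 1.0,
) -> pd.DataFrame:
    """Long-format sweep table: one row per (location, frequency)."""
    frequencies_hz = np.asarray(frequencies_hz, dtype=float)
    if frequencies_hz.size == 0:
        raise ValueError("frequency list must be non-empty")
    if np.any(frequencies_hz < 0):
        raise ValueError("frequencies must be non-negative")
    if not isinstance(locations, dict):
        locations = {name: resolve_location(model.graph, name) for name in locations}
    rows = []
    for f in frequencies_hz:
        prof = solve_frequency(model, StimulusSpec(e0=e0, frequency_hz=float(f), axis=axis))
        for name, idx in locations.items():
            rows.append(
                {
                    "location": name,
                    "region": str(model.graph.region[idx]),
                    "path_distance_um": float(model.graph.path_dist_um[idx]),
                    "frequency_hz": float(f),
                    "sensitivity_mV_per_Vm": float(prof.amplitude[idx]),
                    "phase_rad": float(prof.phase[idx]),
                }
            )
    return pd.DataFrame(rows)


def characterize_resonance(
    sweep: pd.DataFrame, location: str, baseline_hz: float = 0.5
) -> ResonanceSummary:
    sub = sweep[sweep["location"] == location]
    if sub.empty:
        raise KeyError(
            f"unknown location {location!r}; available: {sorted(sweep['location'].unique())}"
        )
    return detect_resonance(
        sub["frequency_hz"].to_numpy(),
        sub["sensitivity_mV_per_Vm"].to_numpy(),
        baseline_hz=baseline_hz,
        location=location,
    )


# ---------------------------------------------------------------------------
# Config-driven experiment


_TOP_KEYS = {"schema_version", "seed", "morphology", "membrane", "stimulus", "locations", "output"}
_MEMBRANE_KEYS = {"g_l_uS_per_cm2", "c_m_uF_per_cm2", "e_l_mV", "r_axial_ohm_cm",
                  "spine_scale", "channels", "shunt", "add_uniform_uS_per_cm2", "v_rest_mV"}
_CHANNEL_KEYS = {"kind", "name", "mu_star", "tau_w_ms", "distribution", "ratio",
                 "g_uS_per_cm2", "e_rev_mV", "v_half_mV", "slope_mV", "frozen"}


def _check_keys(block: dict, allowed: set, what: str):
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown {what} config keys: {sorted(unknown)}")


def build_from_config(cfg: dict):
    """Build (model, axis) from a validated experiment config dict."""
    _check_keys(cfg, _TOP_KEYS, "top-level")
    seed = int(cfg.get("seed", 0))
    morph = cfg.get("morphology", {})
    mem = dict(cfg.get("membrane", {}))
    _check_keys(mem, _MEMBRANE_KEYS, "membrane")
    r_axial = float(mem.get("r_axial_ohm_cm", 100.0))

    _check_keys(morph, {"swc", "synthetic", "max_length_um"}, "morphology")
    if "swc" in morph:
        pts = read_swc(morph["swc"])
        bound = float(morph.get("max_length_um", 10.0))
    elif "synthetic" in morph:
        spec = dict(morph["synthetic"])
        kind = spec.pop("kind")
        if kind == "straight":
            cspec = synthetic.CableSpec(**spec)
            pts, cable_mem = synthetic.make_straight_cable(cspec)
            mem.setdefault("g_l_uS_per_cm2", cable_mem["g_l"] * 1e6)
            mem.setdefault("c_m_uF_per_cm2", cable_mem["c_m"])
            bound = synthetic._bound_um(cspec.target_lambda_um)
        elif kind == "bent":
            bspec = synthetic.BentCableSpec(**spec)
            pts = synthetic.make_bent_cable(bspec)
            cable_mem = synthetic.cable_membrane(
                synthetic._cable_spec_for(bspec.lambda_um, bspec.tau_ms, bspec.radius_um))
            mem.setdefault("g_l_uS_per_cm2", cable_mem["g_l"] * 1e6)
            mem.setdefault("c_m_uF_per_cm2", cable_mem["c_m"])
            bound = synthetic._bound_um(bspec.lambda_um)
        elif kind == "star":
            sspec = synthetic.StarSpec(**spec)
            pts = synthetic.make_star_model(sspec)
            cable_mem = synthetic.cable_membrane(
                synthetic._cable_spec_for(sspec.lambda_um, sspec.tau_ms, sspec.radius_um))
            mem.setdefault("g_l_uS_per_cm2", cable_mem["g_l"] * 1e6)
            mem.setdefault("c_m_uF_per_cm2", cable_mem["c_m"])
            bound = synthetic._bound_um(sspec.lambda_um)
        elif kind == "pyramidal":
            spec.setdefault("seed", seed)
            pts = synthetic.make_surrogate_pyramidal(synthetic.SurrogatePyramidalSpec(**spec))
            bound = 10.0
        else:
            raise ValueError(f"unknown synthetic kind {kind!r}")
    else:
        raise ValueError("morphology must specify 'swc' or 'synthetic'")

    graph = build_compartments(pts, bound, r_axial)
    if "spine_scale" in mem:
        ss = mem["spine_scale"]
        graph = scale_membrane_area(graph, float(ss.get("factor", 1.4)),
                                    tuple(ss.get("regions", ("basal", "apical"))))
    g_l = float(mem.get("g_l_uS_per_cm2", 50.0)) * 1e-6
    c_m = float(mem.get("c_m_uF_per_cm2", 1.0))
    e_l = float(mem.get("e_l_mV", -70.0))

    channels = []
    for ch in mem.get("channels", []):
        ch = dict(ch)
        _check_keys(ch, _CHANNEL_KEYS, "channel")
        kind = ch.get("kind", "qa")
        if kind == "qa":
            dist = DistributionSpec(kind=ch.get("distribution", "uniform"),
                                    ratio=float(ch.get("ratio", 60.0)))
            g_w = distribute_conductance(graph, dist, g_l)
            channels.append(QAChannel(
                name=ch.get("name", "qa"),
                g_density=g_w,
                mu_star=float(ch.get("mu_star", 0.0)),
                tau_w_r=float(ch.get("tau_w_ms", 50.0)),
            ))
        elif kind == "gated":
            gated = boltzmann_channel(
                name=ch.get("name", "gated"),
                g_density=float(ch.get("g_uS_per_cm2", 50.0)) * 1e-6,
                e_rev=float(ch["e_rev_mV"]),
                v_half=float(ch["v_half_mV"]),
                slope_mV=float(ch["slope_mV"]),
                tau_w_ms=float(ch.get("tau_w_ms", 50.0)),
            )
            if ch.get("frozen", False):
                gated = freeze_channel(gated, e_l)
            channels.append(gated)
        else:
            raise ValueError(f"unknown channel kind {kind!r}")

    model = build_model(graph, g_l=g_l, c_m=c_m, e_l=e_l, channels=channels)
    if "v_rest_mV" in mem:
        set_uniform_rest(model, float(mem["v_rest_mV"]))
    if "add_uniform_uS_per_cm2" in mem:
        model = add_uniform_conductance(
            model, float(mem["add_uniform_uS_per_cm2"]) * 1e-6,
            v_rest_target=float(mem.get("v_rest_mV", e_l)))
    if "shunt" in mem:
        sh = mem["shunt"]
        idx = resolve_location(graph, sh.get("location", "soma"))
        model = add_shunt(model, idx, float(sh["g_uS"]))

    try:
        axis = compute_field_axis(pts)
    except Exception:
        axis = FieldAxis(direction=np.array([1.0, 0.0, 0.0]), origin=np.zeros(3))
    return model, axis


def run_experiment(config, out_dir=None) -> dict:
    """Run a config-driven sweep + resonance characterization.

    Writes sweep.csv, summary.json and experiment.log into the output
    directory; on failure partial outputs are removed and the error re-raised.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    _check_keys(config, _TOP_KEYS, "top-level")
    stim = dict(config.get("stimulus", {}))
    _check_keys(stim, {"amplitude_V_per_m", "frequencies_hz"}, "stimulus")
    out = Path(out_dir or config.get("output", {}).get("dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    written = []
    handler = logging.FileHandler(out / "experiment.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    written.append(out / "experiment.log")
    try:
        freqs = stim.get("frequencies_hz", "default")
        if isinstance(freqs, str):
            freqs = default_frequency_grid()
        freqs = np.asarray(freqs, dtype=float)
        if np.any(freqs < 0):
            raise ValueError("frequencies must be non-negative")
        e0 = float(stim.get("amplitude_V_per_m", 1.0))
        model, axis = build_from_config(config)
        locations = config.get("locations", ["soma"])
        log.info("model built: %d compartments", model.graph.n)
        sweep = frequency_sweep(model, axis, freqs, locations, e0=e0)
        sweep.to_csv(out / "sweep.csv", index=False)
        written.append(out / "sweep.csv")
        summaries = {}
        baseline_ok = np.any(np.isclose(freqs, 0.5))
        for name in locations:
            if baseline_ok:
                summaries[name] = asdict(characterize_resonance(sweep, name))
            else:
                summaries[name] = None
        cfg_hash = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()
        summary = {
            "config_sha256": cfg_hash,
            "seed": int(config.get("seed", 0)),
            "versions": {
                "fieldpol": __version__,
                "numpy": np.__version__,
                "python": sys.version.split()[0],
            },
            "n_compartments": int(model.graph.n),
            "resonance": summaries,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        written.append(out / "summary.json")
        log.info("experiment complete")
        return summary
    except Exception:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
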