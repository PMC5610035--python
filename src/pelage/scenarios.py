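"""Scenario configuration, named presets, and reproducible run bundles.

A scenario is a flat JSON-compatible dictionary with sections for the two
pathways, follicle geometry, checkpoint thresholds, growth law, lattice
layout, domains, initial conditions, numerics and the master seed.  Loading
fills every omitted key from the package defaults and records the provenance
(``default`` vs ``user``) of each top-level section key; unknown keys and a
dt above the explicit stability bound are configuration errors listing every
violation.

``run_scenario`` executes a validated configuration and writes a bundle
directory: tidy/wide CSV outputs, the transition log, pattern metrics, and a
JSON metadata echo (resolved config, seed, package version).  A rerun with
the same configuration and seed reproduces the outputs byte-identically.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import pathlib
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from ._engine import stability_limit
from .hf_core import (
    GrowthLaw,
    HFGeometry,
    PathwayParams,
    Phase,
    PhaseThresholds,
    default_params,
    inhibitor_strength_scan,
    phase_durations,
    simulate_hf,
)
from .population import (
    DomainSpec,
    InitialConditionSpec,
    Lattice,
    build_lattice,
    make_hyper_refractory,
    simulate_population,
)
from . import pattern_analysis as pa

__all__ = [
    "ScenarioConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "preset",
    "PRESETS",
    "run_scenario",
]


class ConfigError(ValueError):
    """Invalid scenario configuration; the message lists every violation."""


def _pathway_dict(p: PathwayParams) -> dict:
    return {
        "diffusion_coeff": p.diffusion_coeff,
        "production_region1": p.production_region1,
        "production_region2": {
            "telogen": p.production_region2[Phase.TELOGEN],
            "anagen": p.production_region2[Phase.ANAGEN],
        },
        "bind_on": p.bind_on,
        "bind_off": p.bind_off,
        "degradation": p.degradation,
        "receptor_total": p.receptor_total,
        "noise_amplitude": p.noise_amplitude,
        "extra_source_region1": p.extra_source_region1,
    }


def _pathway_from(d: Mapping) -> PathwayParams:
    sched = d["production_region2"]
    return PathwayParams(
        diffusion_coeff=d["diffusion_coeff"],
        production_region1=d["production_region1"],
        production_region2={Phase.TELOGEN: sched["telogen"],
                            Phase.ANAGEN: sched["anagen"]},
        bind_on=d["bind_on"],
        bind_off=d["bind_off"],
        degradation=d["degradation"],
        receptor_total=d["receptor_total"],
        noise_amplitude=d["noise_amplitude"],
        extra_source_region1=d["extra_source_region1"],
    )


def default_config() -> dict:
    act, inh, geom, thr, law = default_params()
    return {
        "kind": "single",               # single | lattice | scan
        "activator": _pathway_dict(act),
        "inhibitor": _pathway_dict(inh),
        "geometry": {
            "grid_spacing": geom.grid_spacing,
            "length_min": geom.length_min,
            "length_max": geom.length_max,
            "region1_interval": list(geom.region1_interval),
            "region2_width": geom.region2_width,
        },
        "thresholds": {
            "activation_threshold": thr.activation_threshold,
            "termination_threshold": thr.termination_threshold,
            "refractory_min_duration": thr.refractory_min_duration,
        },
        "growth": {
            "v_max": law.v_max,
            "c_half": law.c_half,
            "catagen_speed": law.catagen_speed,
            "threshold": law.threshold,
        },
        "lattice": {
            "rows": 1,
            "cols": 1,
            "coupling_strength": 0.3,
            "periodic_lateral": False,
            "barriers": [],
            "holes": [],
        },
        "domains": [],                  # [] = one uniform background domain
        "init": {
            "base_lead": 5.0,
            "head_tail_span": 0.0,
            "lateral_span": 0.0,
            "jitter_sd": 0.0,
            "domain_delays": {},
            "gradient_domains": None,
            "source_sites": [],
            "source_lead": 0.25,
        },
        "scan": {"levels": [0.5, 0.75, 1.0, 1.25, 1.4, 4.0]},
        "numerics": {"dt": 0.0125, "horizon": 400.0, "output_stride": 0.25},
        "seed": 0,
    }


_DOMAIN_KEYS = {"name", "cols", "rows", "receptor_scale", "rate_scale",
                "inhibitor_production_scale", "threshold_overrides",
                "hyper_refractory_elevation"}


@dataclasses.dataclass
class ScenarioConfig:
    """A fully resolved scenario: raw dict plus typed accessors."""

    data: dict
    provenance: dict

    # -- typed views ------------------------------------------------------

    @property
    def kind(self) -> str:
        return self.data["kind"]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def pathways(self) -> tuple[PathwayParams, PathwayParams]:
        return _pathway_from(self.data["activator"]), _pathway_from(self.data["inhibitor"])

    def geometry(self) -> HFGeometry:
        g = self.data["geometry"]
        return HFGeometry(
            grid_spacing=g["grid_spacing"],
            length_min=g["length_min"],
            length_max=g["length_max"],
            region1_interval=tuple(g["region1_interval"]),
            region2_width=g["region2_width"],
        )

    def thresholds(self) -> PhaseThresholds:
        return PhaseThresholds(**self.data["thresholds"])

    def growth_law(self) -> GrowthLaw:
        return GrowthLaw(**self.data["growth"])

    def domains(self) -> list[DomainSpec]:
        rows = self.data["lattice"]["rows"]
        cols = self.data["lattice"]["cols"]
        out = []
        for d in self.data["domains"]:
            mask = None
            if d.get("cols") is not None or d.get("rows") is not None:
                mask = np.zeros((rows, cols), dtype=bool)
                c0, c1 = d.get("cols") or (0, cols - 1)
                r0, r1 = d.get("rows") or (0, rows - 1)
                mask[r0:r1 + 1, c0:c1 + 1] = True
            spec = DomainSpec(
                name=d["name"],
                mask=mask,
                receptor_scale=d.get("receptor_scale", 1.0),
                rate_scale=d.get("rate_scale", 1.0),
                inhibitor_production_scale=d.get("inhibitor_production_scale", 1.0),
                threshold_overrides=d.get("threshold_overrides", {}),
            )
            elev = d.get("hyper_refractory_elevation", 1.0)
            if elev != 1.0:
                spec = make_hyper_refractory(spec, elev)
            out.append(spec)
        return out

    def lattice(self) -> Lattice:
        lat = self.data["lattice"]
        act, inh = self.pathways()
        return build_lattice(
            (lat["rows"], lat["cols"]),
            self.domains() or None,
            barriers=[tuple(b) for b in lat["barriers"]],
            holes=[tuple(h) for h in lat["holes"]],
            coupling_strength=lat["coupling_strength"],
            periodic_lateral=lat["periodic_lateral"],
            geometry=self.geometry(),
            base_act=act,
            base_inh=inh,
            base_thresholds=self.thresholds(),
            growth_law=self.growth_law(),
        )

    def init_spec(self) -> InitialConditionSpec:
        d = self.data["init"]
        return InitialConditionSpec(
            base_lead=d["base_lead"],
            head_tail_span=d["head_tail_span"],
            lateral_span=d["lateral_span"],
            jitter_sd=d["jitter_sd"],
            domain_delays=dict(d["domain_delays"]),
            gradient_domains=(tuple(d["gradient_domains"])
                              if d["gradient_domains"] is not None else None),
            source_sites=tuple(tuple(s) for s in d["source_sites"]),
            source_lead=d["source_lead"],
        )


def _validate(data: dict) -> list[str]:
    ref = default_config()
    errors = []
    for key in data:
        if key not in ref:
            errors.append(f"unknown section '{key}'")
    for section, value in data.items():
        if section not in ref or not isinstance(ref[section], dict):
            continue
        if section == "domains":
            continue
        if not isinstance(value, dict):
            errors.append(f"section '{section}' must be a mapping")
            continue
        for k in value:
            if k not in ref[section]:
                errors.append(f"unknown key '{section}.{k}'")
    for d in data.get("domains", []):
        for k in d:
            if k not in _DOMAIN_KEYS:
                errors.append(f"unknown key 'domains[].{k}'")
    if data.get("kind", "single") not in ("single", "lattice", "scan"):
        errors.append(f"kind must be single|lattice|scan, got {data.get('kind')!r}")
    # stability bound
    try:
        dt = data["numerics"]["dt"]
        dx = data["geometry"]["grid_spacing"]
        max_D = max(data["activator"]["diffusion_coeff"],
                    data["inhibitor"]["diffusion_coeff"])
        limit = stability_limit(dx, max_D)
        if dt > limit * (1 + 1e-12):
            errors.append(
                f"numerics.dt={dt:g} violates the stability bound "
                f"grid_spacing^2/(2 max D) = {limit:g}"
            )
    except (KeyError, TypeError):
        errors.append("could not evaluate the dt stability bound "
                      "(malformed numerics/geometry/pathway sections)")
    return errors


def _merge(base: dict, user: dict, provenance: dict, prefix: str = "") -> dict:
    out = copy.deepcopy(base)
    for k, v in user.items():
        path = f"{prefix}{k}"
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _merge(base[k], v, provenance, prefix=path + ".")
        else:
            out[k] = copy.deepcopy(v)
            provenance[path] = "user"
    return out


def load_config(source: str | pathlib.Path | Mapping | None = None,
                preset_name: str | None = None,
                overrides: Mapping | None = None) -> ScenarioConfig:
    """Load and validate a scenario configuration.

    ``source`` may be a JSON file path, a mapping, or None (all defaults).
    ``preset_name`` starts from a named preset instead of the bare defaults.
    An empty file or mapping yields the fully-resolved default scenario.
    """
    if isinstance(source, (str, pathlib.Path)):
        text = pathlib.Path(source).read_text().strip()
        user = json.loads(text) if text else {}
    elif source is None:
        user = {}
    else:
        user = dict(copy.deepcopy(source))

    base = preset(preset_name) if preset_name else default_config()
    provenance: dict[str, str] = {}
    merged = _merge(base, user, provenance)
    if overrides:
        merged = _merge(merged, dict(overrides), provenance)
    errors = _validate(merged)
    if errors:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))
    for key in default_config():
        provenance.setdefault(key, "preset" if preset_name else "default")
    return ScenarioConfig(data=merged, provenance=provenance)


def save_config(cfg: ScenarioConfig, path: str | pathlib.Path) -> None:
    pathlib.Path(path).write_text(json.dumps(cfg.data, indent=2, sort_keys=True) + "\n")


# ----------------------------------------------------------------- presets


def _preset_single() -> dict:
    cfg = default_config()
    cfg["numerics"]["horizon"] = 420.0
    return cfg


def _preset_scan() -> dict:
    cfg = default_config()
    cfg["kind"] = "scan"
    cfg["numerics"]["horizon"] = 420.0
    return cfg


def _preset_two_domain() -> dict:
    """Ventral | Dorsal | Ventral stripe lattice with dorsal head-to-tail
    asynchrony and delayed, faster-cycling ventral flanks."""
    cfg = default_config()
    cfg["kind"] = "lattice"
    cfg["activator"]["noise_amplitude"] = 0.002
    cfg["inhibitor"]["noise_amplitude"] = 0.002
    rows, cols, vw = 16, 18, 5
    cfg["lattice"].update({"rows": rows, "cols": cols, "coupling_strength": 0.55})
    cfg["domains"] = [
        {"name": "VentralLeft", "cols": [0, vw - 1],
         "receptor_scale": 2.0, "rate_scale": 1.4},
        {"name": "VentralRight", "cols": [cols - vw, cols - 1],
         "receptor_scale": 2.0, "rate_scale": 1.4},
        {"name": "Dorsal"},
    ]
    cfg["init"].update({
        "base_lead": 6.0,
        "head_tail_span": 6.0,
        "jitter_sd": 2.0,
        "gradient_domains": ["Dorsal"],
        "domain_delays": {"VentralLeft": 3.5, "VentralRight": 3.5},
    })
    cfg["numerics"]["horizon"] = 420.0
    return cfg


def _preset_homogeneous_grid() -> dict:
    """Homogeneous lattice with a built-in head-to-tail onset gradient."""
    cfg = default_config()
    cfg["kind"] = "lattice"
    cfg["activator"]["noise_amplitude"] = 0.0015
    cfg["inhibitor"]["noise_amplitude"] = 0.0015
    cfg["lattice"].update({"rows": 16, "cols": 16, "coupling_strength": 0.25})
    cfg["init"].update({"base_lead": 5.0, "head_tail_span": 8.0, "jitter_sd": 0.3})
    cfg["numerics"]["horizon"] = 1150.0
    return cfg


def _wave_config(cfg: dict, rows: int, cols: int) -> None:
    """Shared wave-scenario operating point.

    The activation threshold is raised close to the competent-telogen
    plateau of the growth signal, so follicles sit quasi-stationary near
    the checkpoint and an arriving activator pulse fires them promptly:
    the anagen front then travels as a genuine excitable-medium wave
    instead of racing the sites' own maturation.
    """
    cfg["thresholds"]["activation_threshold"] = 0.42
    cfg["init"].update({
        "base_lead": 25.0,
        "source_sites": [[0, c] for c in range(cols)],
        "source_lead": 0.25,
    })


def _preset_barrier() -> dict:
    """Anagen wave launched at the head row against a partial barrier
    segment; the wave passes only around the segment's ends."""
    cfg = default_config()
    cfg["kind"] = "lattice"
    rows, cols = 18, 15
    cfg["lattice"].update({"rows": rows, "cols": cols, "coupling_strength": 0.55})
    cfg["lattice"]["barriers"] = [[8, c] for c in range(2, 13)]
    _wave_config(cfg, rows, cols)
    cfg["numerics"]["horizon"] = 45.0
    return cfg


def _preset_aperture() -> dict:
    """Full barrier row with a small aperture; the wave squeezes through
    and bows outward behind the hole."""
    cfg = default_config()
    cfg["kind"] = "lattice"
    rows, cols = 18, 15
    cfg["lattice"].update({"rows": rows, "cols": cols, "coupling_strength": 0.55})
    cfg["lattice"]["barriers"] = [[8, c] for c in range(cols) if c not in (6, 7, 8)]
    _wave_config(cfg, rows, cols)
    cfg["numerics"]["horizon"] = 45.0
    return cfg


def _preset_ear() -> dict:
    """Normal stripe beside a hyper-refractory (ear-like) stripe; waves in
    the normal stripe stop at the domain boundary."""
    cfg = default_config()
    cfg["kind"] = "lattice"
    rows, cols = 16, 13
    cfg["lattice"].update({"rows": rows, "cols": cols, "coupling_strength": 0.55})
    cfg["domains"] = [
        {"name": "Ear", "cols": [8, 12], "hyper_refractory_elevation": 4.0},
        {"name": "Dorsal"},
    ]
    _wave_config(cfg, rows, 8)
    cfg["numerics"]["horizon"] = 45.0
    return cfg


PRESETS = {
    "single_follicle": _preset_single,
    "inhibitor_scan": _preset_scan,
    "homogeneous_grid": _preset_homogeneous_grid,
    "two_domain": _preset_two_domain,
    "barrier": _preset_barrier,
    "aperture": _preset_aperture,
    "hyper_refractory_ear": _preset_ear,
}


def preset(name: str) -> dict:
    try:
        return PRESETS[name]()
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None


# ------------------------------------------------------------------- runs


def run_scenario(cfg: ScenarioConfig, out_dir: str | pathlib.Path) -> dict:
    """Execute a scenario and write its output bundle.

    Returns a small summary dict (also embedded in meta.json).
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    num = cfg.data["numerics"]
    summary: dict[str, Any] = {"kind": cfg.kind, "seed": cfg.seed}

    if cfg.kind == "single":
        act, inh = cfg.pathways()
        traj = simulate_hf(act, inh, cfg.geometry(), cfg.thresholds(),
                           horizon=num["horizon"], dt=num["dt"], seed=cfg.seed,
                           growth_law=cfg.growth_law(),
                           output_stride=num["output_stride"])
        traj.to_frame().to_csv(out / "trajectory.csv", index=False)
        traj.transitions.to_csv(out / "transitions.csv", index=False)
        dur = phase_durations(traj) if len(traj.transitions) >= 3 else pd.DataFrame()
        dur.to_csv(out / "phase_durations.csv", index=False)
        summary["n_complete_cycles"] = int(len(dur))

    elif cfg.kind == "scan":
        act, inh = cfg.pathways()
        tab = inhibitor_strength_scan(
            (act, inh, cfg.geometry(), cfg.thresholds(), cfg.growth_law()),
            levels=cfg.data["scan"]["levels"],
            horizon=num["horizon"], dt=num["dt"],
        )
        tab.to_csv(out / "scan.csv", index=False)
        summary["n_levels"] = int(len(tab))
        summary["n_cycling"] = int(tab["cycling"].sum())

    else:  # lattice
        lattice = cfg.lattice()
        record = simulate_population(lattice, cfg.init_spec(),
                                     horizon=num["horizon"], dt=num["dt"],
                                     seed=cfg.seed,
                                     output_stride=num["output_stride"])
        _write_record(record, out)
        metrics = _pattern_metrics(record)
        metrics.to_csv(out / "metrics.csv", index=False)
        summary["n_sites"] = record.n_sites
        summary["n_complete_cycles"] = pa.n_complete_cycles(record)

    meta = {
        "config": cfg.data,
        "provenance": cfg.provenance,
        "seed": cfg.seed,
        "version": __version__,
        "summary": summary,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return summary


def _write_record(record, out: pathlib.Path) -> None:
    cols = [f"site_{r}_{c}" for r, c in record.site_coords]
    for name, arr in (("phase", record.phase), ("length", record.length),
                      ("signal", record.signal)):
        df = pd.DataFrame(arr, columns=cols)
        df.insert(0, "time", record.times)
        df.to_csv(out / f"{name}.csv", index=False)
    record.transitions.to_csv(out / "transitions.csv", index=False)


def _record_from_bundle(bundle: pathlib.Path):
    """Rebuild a PatternRecord (lattice + histories) from a stored bundle."""
    from .population import PatternRecord

    meta = json.loads((bundle / "meta.json").read_text())
    cfg = ScenarioConfig(data=meta["config"], provenance=meta.get("provenance", {}))
    lattice = cfg.lattice()
    frames = {name: pd.read_csv(bundle / f"{name}.csv")
              for name in ("phase", "length", "signal")}
    times = frames["phase"]["time"].to_numpy()
    tr = pd.read_csv(bundle / "transitions.csv")
    return PatternRecord(
        times=times,
        phase=frames["phase"].iloc[:, 1:].to_numpy(dtype=np.int8),
        length=frames["length"].iloc[:, 1:].to_numpy(),
        signal=frames["signal"].iloc[:, 1:].to_numpy(),
        transitions=tr,
        lattice=lattice,
        site_coords=lattice.site_coords,
    )


def _pattern_metrics(record) -> pd.DataFrame:
    rows = []
    ncyc = pa.n_complete_cycles(record)
    for c in range(1, ncyc + 1):
        rows.append({"cycle": c, "metric": "onset_spread",
                     "value": float(np.ptp(pa.onset_map(record, c).values()))})
    if record.lattice.shape[1] >= 2:
        for s in pa.bilateral_symmetry(record):
            rows.append({"cycle": s.cycle, "metric": "bilateral_symmetry",
                         "value": s.score})
    k = pa.asynchrony_persistence(record)
    rows.append({"cycle": np.nan, "metric": "asynchrony_persistence_cycles",
                 "value": float(k)})
    return pd.DataFrame(rows)
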