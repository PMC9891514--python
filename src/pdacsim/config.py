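"""Run configuration: schema, loading, overrides, resolved dumps.

A run config is a nested mapping with blocks mirroring the model
components (vcbm, death, grid, release, protocol, run).  Configs load from
YAML or JSON; CLI overrides use dotted paths (``vcbm.phi=0.04``).  Every
workflow writes back its fully resolved config so a run is reproducible
from (config, seed) alone.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from pathlib import Path

import yaml

from .agents import DeathParams, VCBMParams
from .dosing import Protocol
from .fibre import ReleaseLaw

DEFAULTS: dict = {
    "seed": 0,
    "vcbm": dataclasses.asdict(VCBMParams()),
    "death": dataclasses.asdict(DeathParams()),
    "grid": {"voxels_per_unit": 1.0, "margin": 5.0, "depth_h": 1.0,
             "D": 12.0, "lam": 0.1, "nu_c": 0.05},
    "release": dataclasses.asdict(ReleaseLaw()),
    "protocol": {"kind": "none", "n_sites": 1, "d_m_mm": 0.0,
                 "dose_ug": 500.0, "start_volume_mm3": 100.0,
                 "fibre_r_total": 0.05, "fibre_length_mm": 5.0,
                 "fibre_annuli": 24},
    "run": {"n_rows": 40, "n_cols": 40, "spacing": 1.0, "sigma": 0.1728,
            "grow_hours": 792, "treat_hours": 792, "dt_pde": 0.1,
            "record_every": 24, "expand_margin": 10.0},
}

_VALID_PROTOCOLS = ("none", "injection", "fibre")
_VALID_RELEASE = ("fvm", "constant", "exponential", "emax", "imax")


class ConfigError(ValueError):
    pass


def load_config(path=None, overrides=()) -> dict:
    """Merge defaults <- file <- dotted overrides, then validate."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data)}")
        _merge(cfg, data)
    for ov in overrides:
        if "=" not in ov:
            raise ConfigError(f"override {ov!r} is not key=value")
        key, _, value = ov.partition("=")
        _set_dotted(cfg, key.strip(), yaml.safe_load(value))
    validate_config(cfg)
    return cfg


def _merge(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _merge(base[k], v)
        else:
            base[k] = v


def _set_dotted(cfg: dict, dotted: str, value) -> None:
    parts = dotted.split(".")
    node = cfg
    for p in parts[:-1]:
        node = node.setdefault(p, {})
        if not isinstance(node, dict):
            raise ConfigError(f"cannot descend into {p!r} of {dotted!r}")
    node[parts[-1]] = value


def validate_config(cfg: dict) -> None:
    proto = cfg["protocol"]
    if proto["kind"] not in _VALID_PROTOCOLS:
        raise ConfigError(f"protocol.kind must be one of {_VALID_PROTOCOLS}")
    if cfg["release"]["kind"] not in _VALID_RELEASE:
        raise ConfigError(f"release.kind must be one of {_VALID_RELEASE}")
    try:
        vcbm_params(cfg)
        death_params(cfg)
        release_law(cfg)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    if cfg["run"]["dt_pde"] <= 0:
        raise ConfigError("run.dt_pde must be positive")


def vcbm_params(cfg: dict) -> VCBMParams:
    return VCBMParams(**cfg["vcbm"])


def death_params(cfg: dict) -> DeathParams:
    return DeathParams(**cfg["death"])


def release_law(cfg: dict) -> ReleaseLaw:
    return ReleaseLaw(**cfg["release"])


def protocol(cfg: dict) -> Protocol:
    p = cfg["protocol"]
    return Protocol(kind=p["kind"], n_sites=p["n_sites"], d_m=p["d_m_mm"],
                    total_dose=p["dose_ug"],
                    release=release_law(cfg) if p["kind"] == "fibre" else None,
                    start_volume=p["start_volume_mm3"],
                    fibre_r_total=p["fibre_r_total"],
                    fibre_length_mm=p["fibre_length_mm"],
                    fibre_annuli=p["fibre_annuli"])


def dump_resolved(cfg: dict, path) -> None:
    Path(path).write_text(json.dumps(cfg, indent=2, default=float))
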