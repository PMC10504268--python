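"""Configuration loading and validation for the pipeline.

A configuration is a nested mapping with sections ``model``, ``grid``,
``run``, ``occupancy``, ``induction``, ``growth``, ``synth`` and
``analysis``; unknown sections or keys are rejected with their location so
typos fail loudly.  ``load_config`` deep-merges a user file (YAML or JSON)
over the packaged defaults; every pipeline run writes the fully resolved
configuration next to its outputs.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import yaml

from .mindyn import MinModelParams
from .occupancy import OccupancyConfig
from .sizemodel import GrowthParams, InductionParams
from .synthdata import LineageConfig

__all__ = ["default_config", "load_config", "resolve", "ConfigError"]


class ConfigError(ValueError):
    pass


_SECTION_KEYS = {
    "config_version": None,
    "model": {"D_D", "D_E", "D_m", "sigma_D", "sigma_dD", "sigma_E",
              "sigma_de", "k_exchange", "dens_D", "dens_E", "geometry_factor"},
    "grid": {"dx", "L", "n_x"},
    "run": {"t_end", "sample_dt", "burn_in", "perturbation", "seed",
            "out_dir", "format", "scan_multipliers", "scan_lengths", "scan_base_dens_E"},
    "occupancy": {"window_w", "threshold_mode", "theta", "burn_in"},
    "induction": {"minE_initial", "minE_final", "t_c", "t_s", "time_unit"},
    "growth": {"alpha", "tau", "lopt_a", "lopt_b"},
    "synth": {"n_lineages", "n_generations", "alpha_mean", "alpha_cv",
              "tau_mean", "tau_cv", "division_fraction_sd", "lstable_cv",
              "induction_start_gen", "lopt_a", "lopt_b", "sampling_interval",
              "ring_plateau", "ring_rate_pre", "ring_rate_post",
              "ring_threshold_fraction", "intensity_noise_sd",
              "background_mean", "seed"},
    "analysis": {"threshold_fraction", "induction_gen"},
}


def default_config() -> dict:
    with resources.files("minsize.data").joinpath("defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


def _validate(cfg: dict) -> None:
    for section, val in cfg.items():
        if section not in _SECTION_KEYS:
            raise ConfigError(f"unknown config section {section!r}")
        allowed = _SECTION_KEYS[section]
        if allowed is None:
            continue
        if not isinstance(val, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        for key in val:
            if key not in allowed:
                raise ConfigError(f"unknown key {section}.{key}")


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Packaged defaults, optionally overridden by a YAML/JSON file."""
    cfg = default_config()
    if path is not None:
        text = Path(path).read_text()
        user = (json.loads(text) if str(path).endswith(".json")
                else yaml.safe_load(text))
        if not isinstance(user, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        _validate(user)
        cfg = _merge(cfg, user)
    _validate(cfg)
    return cfg


def resolve(cfg: dict):
    """Instantiate the typed parameter objects from a validated config."""
    model = MinModelParams(**cfg["model"])
    occ = OccupancyConfig(**cfg["occupancy"])
    induction = InductionParams(**cfg["induction"])
    growth = GrowthParams(**cfg["growth"])
    synth_kw = dict(cfg["synth"])
    synth_kw.setdefault("alpha_mean", growth.alpha)
    synth_kw.setdefault("tau_mean", growth.tau)
    synth_kw.setdefault("lopt_a", growth.lopt_a)
    synth_kw.setdefault("lopt_b", growth.lopt_b)
    synth = LineageConfig(induction=induction, **synth_kw)
    return dict(model=model, occupancy=occ, induction=induction,
                growth=growth, synth=synth,
                grid=cfg["grid"], run=cfg["run"], analysis=cfg["analysis"])


def dump_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
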