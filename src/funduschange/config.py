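"""Nested run configuration with YAML loading and strict key validation.

Precedence: explicit overrides (CLI flags) > config file > defaults.  The
fully resolved configuration is persisted alongside every run's outputs so
results are reproducible from the run directory alone.
"""

from __future__ import annotations

import copy
import json
import os

import yaml

DEFAULTS: dict = {
    "io": {
        "channel_policy": "luma",
    },
    "dictionary": {
        "patch_size": 25,
        "window_size": 50,
        "grid": 5,
    },
    "src": {
        "lam": "auto",
        "stride": None,
        "normalize": True,
    },
    "change": {
        "threshold": None,  # None -> 0.3 in src mode, 0.15 in fusion mode
        "open_radius": 1,
        "close_radius": 3,
        "min_area": 20,
        "mode": "src",
    },
    "illumination": {
        "order": 4,
        "robust_iters": 5,
        "tukey_c": 4.685,
        "epsilon": 1e-3,
    },
    "sim": {
        "height": 256,
        "width": 256,
        "seed": 0,
        "n_vessels": 8,
        "vessel_contrast": 0.25,
        "n_lesions": 5,
        "lesion_size_min": 7,
        "lesion_size_max": 15,
        "lesion_contrast": 0.3,
        "blend_alpha": 0.5,
        "gain_order": 2,
        "gain_amplitude": 0.2,
        "bias_amplitude": 0.05,
        "bump_count": 2,
        "bump_sigma": 30.0,
        "noise_sigma": 0.005,
        "jitter": 0.5,
    },
    "eval": {
        "interpolated_map": True,
    },
}


class ConfigError(ValueError):
    """Raised for unknown keys or malformed configuration files."""


def _merge(base: dict, update: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in update.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{here} must be a mapping")
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path: str | os.PathLike | None = None,
                overrides: dict | None = None) -> dict:
    """Resolve the run configuration.

    Parameters
    ----------
    path : path-like, optional
        YAML file with (a subset of) the keys in :data:`DEFAULTS`; unknown
        keys are rejected.
    overrides : dict, optional
        Nested dict applied on top of the file (CLI flags).
    """
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(os.fspath(path)) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def detector_params(cfg: dict) -> dict:
    """Map a resolved config onto SRCChangeDetector keyword arguments."""
    return {
        "patch_size": cfg["dictionary"]["patch_size"],
        "window_size": cfg["dictionary"]["window_size"],
        "grid": cfg["dictionary"]["grid"],
        "lam": cfg["src"]["lam"],
        "stride": cfg["src"]["stride"],
        "normalize": cfg["src"]["normalize"],
        "threshold": cfg["change"]["threshold"],
        "open_radius": cfg["change"]["open_radius"],
        "close_radius": cfg["change"]["close_radius"],
        "min_area": cfg["change"]["min_area"],
        "mode": cfg["change"]["mode"],
        "illum_order": cfg["illumination"]["order"],
        "illum_iters": cfg["illumination"]["robust_iters"],
        "illum_tukey_c": cfg["illumination"]["tukey_c"],
        "illum_epsilon": cfg["illumination"]["epsilon"],
    }


def sim_config(cfg: dict, seed: int | None = None):
    """Build a SimConfig from the resolved config (optionally reseeded)."""
    from .synthetic import SimConfig

    s = cfg["sim"]
    return SimConfig(
        height=s["height"], width=s["width"],
        seed=s["seed"] if seed is None else seed,
        n_vessels=s["n_vessels"], vessel_contrast=s["vessel_contrast"],
        n_lesions=s["n_lesions"],
        lesion_size_range=(s["lesion_size_min"], s["lesion_size_max"]),
        lesion_contrast=s["lesion_contrast"], blend_alpha=s["blend_alpha"],
        gain_order=s["gain_order"], gain_amplitude=s["gain_amplitude"],
        bias_amplitude=s["bias_amplitude"], bump_count=s["bump_count"],
        bump_sigma=s["bump_sigma"], noise_sigma=s["noise_sigma"],
        jitter=s["jitter"],
    )


def dump_config(cfg: dict, path: str | os.PathLike) -> None:
    """Persist a resolved configuration as JSON."""
    with open(os.fspath(path), "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")
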