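"""Run configuration: defaults, YAML loading, schema validation.

Configuration is a flat mapping of dotted keys (``density.heavy_lo``,
``responders.fdr`` ...). A YAML file may be flat or nested; nested sections
are flattened. Every key is validated against the schema before any stage
runs, and the effective configuration is echoed to the run log.
"""

from __future__ import annotations

from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_config", "merge_config", "ConfigError"]


class ConfigError(ValueError):
    """Unknown or ill-typed configuration key."""


DEFAULTS: dict[str, object] = {
    "seed": 0,
    # density / heavy window
    "density.a": 10.9276,
    "density.b": 13.593,
    "density.heavy_lo": 1.7125,
    "density.heavy_hi": 1.755,
    # NB engine
    "nb.ridge_var": 36.0,
    "nb.sf_method": "median_of_ratios",
    # responder detection
    "responders.fdr": 0.10,
    "responders.min_prevalence": 0.45,
    # delta BD
    "deltabd.n_grid": 20,
    # temporal model
    "temporal.fdr": 0.10,
    "temporal.base_mean_min": 1.0,
    # phylogenetic metrics
    "phylo.n_null": 999,
    "phylo.null_model": "label_shuffle",
    "phylo.consensus": 0.90,
    # simulator
    "sim.n_otus": 100,
    "sim.n_labeled": 10,
    "sim.abund_sigma": 1.0,
    "sim.gc_beta_a": 50.0,
    "sim.gc_beta_b": 50.0,
    "sim.atom_excess": 1.0,
    "sim.max_shift": 0.036,
    "sim.profile_sd": 0.004,
    "sim.tail_fraction": 0.05,
    "sim.tail_sd": 0.02,
    "sim.density_lo": 1.67,
    "sim.density_hi": 1.77,
    "sim.n_fractions": 20,
    "sim.depth": 10_000,
    "sim.concentration": 300.0,
    "sim.n_replicates": 3,
}


def _flatten(mapping: dict, prefix: str = "") -> dict[str, object]:
    flat: dict[str, object] = {}
    for key, value in mapping.items():
        full = f"{prefix}{key}"
        if isinstance(value, dict):
            flat.update(_flatten(value, f"{full}."))
        else:
            flat[full] = value
    return flat


def _validate(overrides: dict[str, object]) -> None:
    for key, value in overrides.items():
        if key not in DEFAULTS:
            raise ConfigError(f"unknown configuration key: {key!r}")
        default = DEFAULTS[key]
        if isinstance(default, bool) and not isinstance(value, bool):
            raise ConfigError(f"key {key!r} expects a boolean, got {value!r}")
        if isinstance(default, (int, float)) and not isinstance(value, (int, float)):
            raise ConfigError(f"key {key!r} expects a number, got {value!r}")
        if isinstance(default, str) and not isinstance(value, str):
            raise ConfigError(f"key {key!r} expects a string, got {value!r}")


def load_config(path: str | Path | None) -> dict[str, object]:
    """Load a YAML config file and merge it over the defaults."""
    overrides: dict[str, object] = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        overrides = _flatten(raw)
    return merge_config(overrides)


def merge_config(overrides: dict[str, object]) -> dict[str, object]:
    """Validate overrides and merge them over the defaults."""
    _validate(overrides)
    cfg = dict(DEFAULTS)
    cfg.update(overrides)
    return cfg
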