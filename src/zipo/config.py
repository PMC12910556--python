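"""Configuration resolution, presets, and run manifests.

A configuration is a flat mapping of documented keys. Values resolve with
precedence defaults < config file < command-line overrides. Config files are
YAML: flat ``key: value`` pairs and/or nested sections (``model:``, ``train:``,
``simulate:`` ...) whose inner keys are the same documented keys. Encoder and
library-head structures use the ``s1-s2-...-sp`` convention (e.g.
``"512-256-128"``).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from .data import PreprocessSpec
from .exceptions import ValidationError
from .hyperopt import parse_structure
from .model import ModelSpec
from .simulate import SimSpec
from .training import TrainConfig

__all__ = [
    "DEFAULTS",
    "resolve_config",
    "preset",
    "RunManifest",
    "write_manifest",
    "model_spec_from_config",
    "train_config_from_config",
    "sim_spec_from_config",
    "preprocess_spec_from_config",
]

__version__ = "0.1.0"

DEFAULTS: dict = {
    # model
    "encoder": "2048-1024-512-256-128",
    "residuals": "full",  # none | full | comma-separated block indices
    "activation": "sigmoid",
    "batch_norm": True,
    "distribution": "zip",
    "lib_head": "16-4",
    "alpha_z": 0.1,
    "alpha_w": 0.1,
    "alpha_theta": 0.0,
    # preprocessing
    "log_transform": False,
    "library_normalize": False,
    # training
    "lr_initial": 0.0212,
    "lr_target": 0.001,
    "lr_decay": 0.9,
    "plateau_patience_epochs": 15,
    "plateau_min_improvement": 0.001,
    "plateau_factor": 0.5,
    "early_stop_epochs": 30,
    "batch_size": 128,
    "validation_fraction": 0.1,
    "max_epochs": 500,
    "seed": 0,
    # data io
    "matrix_orientation": "genes-as-rows",
    # simulation
    "n_cells": 500,
    "n_genes": 200,
    "n_factors": 4,
    "lib_log_mean": 2.5,
    "lib_log_sd": 1.15,
    "zero_logit_mean": -1.5,
    "zero_logit_sd": 0.5,
    "dispersion": None,
    "gene_logit_offsets": False,
    # hyperparameter search
    "structures": "2048-1024-512-256-128,1024-512-256-128,"
                  "1024-512-256-128-64,512-256-128,512-256-128-64",
    "alpha_z_low": 0.01,
    "alpha_z_high": 1.0,
    "alpha_w_low": 0.01,
    "alpha_w_high": 1.0,
    "n_trials": 96,
}

PRESETS = {
    "zipo-default": {},
    "dca": {
        "encoder": "128-64",
        "residuals": "none",
        "distribution": "zinb",
        "log_transform": True,
        "library_normalize": True,
    },
    "zipDCA": {
        "encoder": "128-64",
        "residuals": "none",
        "distribution": "zip",
        "log_transform": True,
        "library_normalize": True,
    },
    "tunedDCA": {
        "encoder": "128-64",
        "residuals": "none",
        "distribution": "zip",
        "log_transform": True,
        "library_normalize": True,
        "alpha_z": 0.1,
        "alpha_w": 0.1,
    },
}


def _coerce(key: str, value):
    default = DEFAULTS[key]
    if isinstance(value, str):
        s = value.strip()
        if default is None:  # nullable float (dispersion)
            return None if s.lower() in ("none", "null", "") else float(s)
        if isinstance(default, bool):
            if s.lower() in ("true", "1", "yes", "on"):
                return True
            if s.lower() in ("false", "0", "no", "off"):
                return False
            raise ValidationError(f"cannot parse boolean for key {key!r}: {s!r}")
        if isinstance(default, int) and not isinstance(default, bool):
            try:
                return int(s)
            except ValueError as exc:
                raise ValidationError(
                    f"cannot parse integer for key {key!r}: {s!r}"
                ) from exc
        if isinstance(default, float):
            try:
                return float(s)
            except ValueError as exc:
                raise ValidationError(
                    f"cannot parse number for key {key!r}: {s!r}"
                ) from exc
        return s
    if default is None:
        return None if value is None else float(value)
    if isinstance(default, bool):
        if isinstance(value, bool):
            return value
        raise ValidationError(f"cannot parse boolean for key {key!r}: {value!r}")
    if isinstance(default, (int, float)) and isinstance(value, (int, float)):
        return type(default)(value)
    if isinstance(default, str):
        return str(value)
    return value


def _flatten(mapping: dict) -> dict:
    flat = {}
    for key, value in mapping.items():
        if isinstance(value, dict):
            flat.update(_flatten(value))
        else:
            flat[key] = value
    return flat


def resolve_config(file=None, overrides=None, base: dict | None = None) -> dict:
    """Resolve the full configuration.

    ``overrides`` is a list of ``key=value`` strings (or a mapping); unknown
    keys are rejected by name. Structure strings are validated eagerly.
    """
    cfg = dict(DEFAULTS)
    if base:
        cfg.update(base)
    if file is not None:
        loaded = yaml.safe_load(Path(file).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValidationError("config file must contain a mapping")
        for key, value in _flatten(loaded).items():
            if key not in DEFAULTS:
                raise ValidationError(f"unknown configuration key {key!r}")
            cfg[key] = _coerce(key, value)
    if overrides:
        items = (
            overrides.items()
            if isinstance(overrides, dict)
            else [_split_override(s) for s in overrides]
        )
        for key, value in items:
            if key not in DEFAULTS:
                raise ValidationError(f"unknown configuration key {key!r}")
            cfg[key] = _coerce(key, value)
    for key in ("encoder", "lib_head"):
        try:
            parse_structure(cfg[key])
        except ValidationError as exc:
            raise ValidationError(f"invalid structure for key {key!r}: {exc}") from exc
    return cfg


def _split_override(s: str) -> tuple[str, str]:
    if "=" not in s:
        raise ValidationError(f"override {s!r} is not of the form key=value")
    key, _, value = s.partition("=")
    return key.strip(), value


def preset(name: str) -> dict:
    """Named configuration presets.

    ``zipo-default`` — the deep 2048-1024-512-256-128 encoder with full
    residuals, 128 latents, ZIP, α_z = α_w = 0.1. ``dca`` — the shallow
    128-64(-128) autoencoder shape with ZINB plus log transform and
    library-size input normalization; ``zipDCA`` swaps in ZIP; ``tunedDCA``
    keeps the shallow shape with the tuned regularization.
    """
    if name not in PRESETS:
        raise ValidationError(
            f"unknown preset {name!r}; valid: {sorted(PRESETS)}"
        )
    return resolve_config(base=PRESETS[name])


# -- typed views over a resolved configuration --------------------------------


def model_spec_from_config(cfg: dict, n_genes: int, n_covariates: int = 0) -> ModelSpec:
    residuals = cfg["residuals"]
    if residuals not in ("none", "full"):
        residuals = [int(tok) for tok in str(residuals).split(",")]
    return ModelSpec(
        encoder_sizes=parse_structure(cfg["encoder"]),
        n_genes=n_genes,
        distribution=cfg["distribution"],
        residuals=residuals,
        activation=cfg["activation"],
        batch_norm=cfg["batch_norm"],
        n_covariates=n_covariates,
        lib_head_sizes=parse_structure(cfg["lib_head"]),
        alpha_z=cfg["alpha_z"],
        alpha_w=cfg["alpha_w"],
        alpha_theta=cfg["alpha_theta"],
    )


def train_config_from_config(cfg: dict) -> TrainConfig:
    return TrainConfig(
        lr_initial=cfg["lr_initial"],
        lr_target=cfg["lr_target"],
        lr_decay=cfg["lr_decay"],
        plateau_patience_epochs=cfg["plateau_patience_epochs"],
        plateau_min_improvement=cfg["plateau_min_improvement"],
        plateau_factor=cfg["plateau_factor"],
        early_stop_epochs=cfg["early_stop_epochs"],
        batch_size=cfg["batch_size"],
        validation_fraction=cfg["validation_fraction"],
        max_epochs=cfg["max_epochs"],
        seed=cfg["seed"],
    )


def sim_spec_from_config(cfg: dict) -> SimSpec:
    return SimSpec(
        n_cells=cfg["n_cells"],
        n_genes=cfg["n_genes"],
        n_factors=cfg["n_factors"],
        lib_log_mean=cfg["lib_log_mean"],
        lib_log_sd=cfg["lib_log_sd"],
        zero_logit_mean=cfg["zero_logit_mean"],
        zero_logit_sd=cfg["zero_logit_sd"],
        dispersion=cfg["dispersion"],
        gene_logit_offsets=cfg["gene_logit_offsets"],
        seed=cfg["seed"],
    )


def preprocess_spec_from_config(cfg: dict) -> PreprocessSpec:
    return PreprocessSpec(
        log_transform=cfg["log_transform"],
        library_normalize=cfg["library_normalize"],
    )


@dataclass
class RunManifest:
    subcommand: str
    config_snapshot: dict
    seed: int
    software_version: str
    timestamp: str


def write_manifest(out_dir, subcommand: str, cfg: dict, seed: int) -> Path:
    """Write one JSON manifest next to a run's outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        subcommand=subcommand,
        config_snapshot={k: cfg[k] for k in sorted(cfg)},
        seed=seed,
        software_version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    path = out_dir / f"{subcommand}.manifest.json"
    path.write_text(json.dumps(manifest.__dict__, indent=2) + "\n")
    return path
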