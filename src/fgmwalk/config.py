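"""Configuration loading, scenario presets, and tabular/JSON output.

A model config block is a YAML or JSON mapping with either the
equicorrelated keys ``n, sigma_sq, rho_sigma, m_sq, rho_m, theta, v`` (``v``
a list, or the scalar shortcut ``v1``) or explicit ``sigma_matrix`` /
``m_matrix`` entries.  Scenario presets bundle the parameter sets of the
published figure captions.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from typing import Optional

import numpy as np
import yaml

from .model import ModelSpec, ModelSpecError, correlated_matrix, gamma

__all__ = [
    "ConfigError",
    "load_config",
    "model_from_dict",
    "model_to_dict",
    "dump_config",
    "config_hash",
    "PRESETS",
    "preset_model",
    "run_manifest",
    "write_outputs",
]


class ConfigError(ModelSpecError):
    """Configuration error naming the offending key."""


_MODEL_KEYS = {"n", "sigma_sq", "rho_sigma", "m_sq", "rho_m", "theta", "v",
               "v1", "sigma_matrix", "m_matrix"}


def model_from_dict(cfg: dict) -> ModelSpec:
    unknown = set(cfg) - _MODEL_KEYS
    if unknown:
        raise ConfigError(f"unknown model key(s): {sorted(unknown)}")
    try:
        n = int(cfg["n"])
    except KeyError:
        raise ConfigError("missing required key 'n'") from None
    if "sigma_matrix" in cfg:
        Sigma = np.asarray(cfg["sigma_matrix"], dtype=float)
    else:
        try:
            Sigma = correlated_matrix(n, float(cfg["sigma_sq"]),
                                      float(cfg.get("rho_sigma", 0.0)))
        except KeyError:
            raise ConfigError("missing key 'sigma_sq' (or 'sigma_matrix')") from None
        except ModelSpecError as e:
            raise ConfigError(f"key 'rho_sigma': {e}") from None
    if "m_matrix" in cfg:
        M = np.asarray(cfg["m_matrix"], dtype=float)
    else:
        try:
            M = correlated_matrix(n, float(cfg.get("m_sq", 1.0)),
                                  float(cfg.get("rho_m", 0.0)))
        except ModelSpecError as e:
            raise ConfigError(f"key 'rho_m': {e}") from None
    if "v" in cfg and "v1" in cfg:
        raise ConfigError("give either key 'v' or key 'v1', not both")
    if "v1" in cfg:
        v = np.zeros(n)
        v[0] = float(cfg["v1"])
    elif "v" in cfg:
        v = np.asarray(cfg["v"], dtype=float)
    else:
        raise ConfigError("missing key 'v' (or 'v1')")
    theta = float(cfg.get("theta", 1.0))
    try:
        return ModelSpec(n, Sigma, M, v, theta)
    except ModelSpecError as e:
        raise ConfigError(str(e)) from None


def model_to_dict(model: ModelSpec) -> dict:
    return model.to_dict()


def load_config(path) -> dict:
    """Load and validate a run configuration (YAML or JSON).

    Returns a dict with key ``model`` (a validated ModelSpec), optional
    engine-parameter sub-dicts passed through verbatim, and the derived
    scalars echoed under ``derived``.
    """
    path = pathlib.Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    model_block = raw.get("model", raw)
    model = model_from_dict({k: v for k, v in model_block.items()
                             if k in _MODEL_KEYS})
    out = {"model": model, "raw": raw}
    out["derived"] = {
        "delta_bar_sq": model.delta_bar_sq,
        "m_bar_sq": model.m_bar_sq,
        "gamma": gamma(model),
    }
    for section in ("walk", "ibs"):
        if section in raw:
            out[section] = dict(raw[section])
    return out


def dump_config(model: ModelSpec, path, extra: Optional[dict] = None) -> None:
    doc = {"model": model.to_dict()}
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def config_hash(model: ModelSpec, engine_params: Optional[dict] = None) -> str:
    doc = {"model": model.to_dict(), "engine": engine_params or {}}
    blob = json.dumps(doc, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# standard scenario presets (named after the published panels they reproduce)
# ---------------------------------------------------------------------------

PRESETS: dict = {
    # isotropic slow-change reference scenario
    "fig1": {"n": 2, "sigma_sq": 10.0, "rho_sigma": 0.0, "m_sq": 1.0,
             "rho_m": 0.0, "v1": 1e-5, "theta": 1.0},
    # complexity/speed grid: gamma = 10 * v1
    "fig2": {"n": 2, "sigma_sq": 10.0, "rho_sigma": 0.0, "m_sq": 1.0,
             "rho_m": 0.0, "v1": 1e-5, "theta": 1.0},
    # correlated scenarios: strong mutational / selectional correlation
    "fig4_mut": {"n": 2, "sigma_sq": 10.0, "rho_sigma": 0.0, "m_sq": 1.0,
                 "rho_m": 0.9, "v1": 1e-5, "theta": 1.0},
    "fig4_sel": {"n": 2, "sigma_sq": 10.0, "rho_sigma": 0.9, "m_sq": 1.0,
                 "rho_m": 0.0, "v1": 1e-5, "theta": 1.0},
    # antagonistic correlations (regime switch along v1 in {1e-5, 0.0032, 0.1})
    "fig6": {"n": 2, "sigma_sq": 10.0, "rho_sigma": 0.9, "m_sq": 1.0,
             "rho_m": -0.9, "v1": 1e-5, "theta": 1.0},
}

#: individual-based base parameters (K, L, mu, B)
IBS_BASE = {"K": 1000, "L": 10, "mu": 5e-6, "B": 4}


def preset_model(name: str, **overrides) -> ModelSpec:
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; known: {sorted(PRESETS)}")
    cfg = dict(PRESETS[name])
    cfg.update(overrides)
    return model_from_dict(cfg)


# ---------------------------------------------------------------------------
# outputs
# ---------------------------------------------------------------------------


def run_manifest(model: ModelSpec, seed, engine_params: Optional[dict] = None,
                 extra: Optional[dict] = None) -> dict:
    from . import __version__

    manifest = {
        "package_version": __version__,
        "seed": seed if isinstance(seed, (int, str)) else repr(seed),
        "config_hash": config_hash(model, engine_params),
        "model": model.to_dict(),
        "engine": engine_params or {},
        "derived": {
            "delta_bar_sq": model.delta_bar_sq,
            "m_bar_sq": model.m_bar_sq,
            "gamma": gamma(model),
        },
    }
    if extra:
        manifest.update(extra)
    return manifest


def write_outputs(tables: dict, manifest: dict, out_prefix) -> list:
    """Write each table as <prefix>_<name>.tsv plus <prefix>_manifest.json.

    Tables are pandas DataFrames (or None for an intentionally empty table,
    which still produces a header-only file when columns are known).
    Contents are deterministic given identical inputs.
    """
    out_prefix = pathlib.Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out_prefix.parent / f"{out_prefix.name}_{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.12g")
        written.append(p)
    mp = out_prefix.parent / f"{out_prefix.name}_manifest.json"
    with open(mp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(mp)
    return written
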