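"""YAML/JSON (de)serialization of network and experiment configuration.

The checked-in defaults in :mod:`obpc.network` are the reference profile;
a config file only needs to state overrides.  Structure::

    n_per_type: 100
    dt: 0.5
    cells:
      Mi: {theta_max: 9.0}
    pathways:
      mi_ff: {e_nernst: 70.0, tau1: 1.0, tau2: 2.0}
    curves:
      alpha2_gr: {y_half: 0.1}
    plasticity:
      t_delay: 1.0
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .network import NetworkConfig
from .neuromod import ReceptorCurve
from .plasticity import PlasticityParams

__all__ = [
    "network_config_to_dict",
    "network_config_from_dict",
    "load_network_config",
    "save_network_config",
]


def network_config_to_dict(cfg: NetworkConfig) -> dict:
    return {
        "n_per_type": cfg.n_per_type,
        "dt": cfg.dt,
        "mi_apical_tau": cfg.mi_apical_tau,
        "settle_ms": cfg.settle_ms,
        "window_ms": cfg.window_ms,
        "spike_prob_scale": cfg.spike_prob_scale,
        "osn_gain": cfg.osn_gain,
        "cells": {k: dataclasses.asdict(v) for k, v in cfg.cells.items()},
        "pathways": {k: dataclasses.asdict(v) for k, v in cfg.pathways.items()},
        "curves": {k: dataclasses.asdict(v) for k, v in cfg.curves.items()},
        "plasticity": dataclasses.asdict(cfg.plasticity),
    }


def network_config_from_dict(data: dict | None) -> NetworkConfig:
    """Build a config from a (possibly partial) mapping of overrides."""
    cfg = NetworkConfig()
    data = data or {}
    scalars = {k: data[k] for k in
               ("n_per_type", "dt", "mi_apical_tau", "settle_ms", "window_ms",
                "spike_prob_scale", "osn_gain")
               if k in data}
    cells = dict(cfg.cells)
    for name, over in (data.get("cells") or {}).items():
        if name not in cells:
            raise KeyError(f"unknown population {name!r}")
        cells[name] = dataclasses.replace(cells[name], **over)
    pathways = dict(cfg.pathways)
    for name, over in (data.get("pathways") or {}).items():
        if name not in pathways:
            raise KeyError(f"unknown pathway {name!r}")
        pathways[name] = dataclasses.replace(pathways[name], **over)
    curves = dict(cfg.curves)
    for name, over in (data.get("curves") or {}).items():
        curves[name] = ReceptorCurve(name=name, y_half=float(over["y_half"]))
    plasticity = dataclasses.replace(cfg.plasticity,
                                     **(data.get("plasticity") or {}))
    return NetworkConfig(cells=cells, pathways=pathways, curves=curves,
                         plasticity=plasticity, **scalars)


def load_network_config(path) -> NetworkConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return network_config_from_dict(data)


def save_network_config(cfg: NetworkConfig, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(network_config_to_dict(cfg), fh, sort_keys=True)
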