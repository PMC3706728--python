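"""Configuration handling and the standard experiment presets.

Configs are flat YAML key-value documents.  Keys matching
:class:`~astrowave.params.ModelParams` fields override model constants;
keys matching :class:`~astrowave.simulate.SimulationConfig` fields control
the run (duration, dt, stimulus, geometry).  Unknown keys are rejected.

The experiment presets bundle the calibrated working parameterization used
for the three standard protocols: a single stimulated cell, a glutamate-
stimulated network, and the amyloid-β (increased calcium leak) network.
"""

from __future__ import annotations

import dataclasses
import json
import hashlib
import time
from pathlib import Path

import numpy as np
import yaml

from .geometry import CellField, load_positions
from .params import ModelParams
from .simulate import SimulationConfig

__all__ = [
    "WORKING_PARAMS",
    "working_params",
    "load_config",
    "save_config",
    "experiment_presets",
    "RunManifest",
    "write_manifest",
]

# Calibrated working values for the fitted constants (see docs/methods.md):
# the extracellular leak is pinned by the resting balance j_PCA(C_rest) =
# j_l_ext at C_rest = 0.01 μM (half the ATP-release threshold C_min), the
# basal IP3 level I0 by the resting ER flux balance at C_ER = 400 μM, and
# the receptor domain area / ATP release strength by the network transition
# behavior under glutamate.
K_L_EXT_FIT = 0.046183663822398824   # μM/s
I0_FIT = 0.002                       # μM
GPCR_AREA_FIT = 9.0                  # μm²
J_ATP_MAX_FIT = 13000.0              # areal release strength

_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}
_SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)} - {
    "params", "cells"
}


def working_params(**overrides) -> ModelParams:
    """The calibrated parameterization used by the experiment presets."""
    base = dict(k_l_ext=K_L_EXT_FIT, I0=I0_FIT, gpcr_area=GPCR_AREA_FIT,
                j_atp_max=J_ATP_MAX_FIT)
    base.update(overrides)
    return ModelParams(**base)


WORKING_PARAMS = working_params()


def load_config(path) -> SimulationConfig:
    """Load a flat YAML config into a validated SimulationConfig."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return config_from_dict(doc, source=str(path))


def config_from_dict(doc: dict, source: str = "<dict>") -> SimulationConfig:
    param_kw, sim_kw = {}, {}
    cells = None
    for key, val in doc.items():
        if key == "positions_file":
            cells = load_positions(val)
        elif key in _PARAM_FIELDS:
            param_kw[key] = val
        elif key in _SIM_FIELDS:
            sim_kw[key] = val
        else:
            raise KeyError(f"{source}: unknown config key {key!r}")
    params = ModelParams(**param_kw)
    cfg = SimulationConfig(params=params, cells=cells, **sim_kw)
    cfg.validate()
    return cfg


def config_to_dict(cfg: SimulationConfig) -> dict:
    doc = {}
    defaults = ModelParams()
    for f in dataclasses.fields(ModelParams):
        v = getattr(cfg.params, f.name)
        if v != getattr(defaults, f.name):
            doc[f.name] = v
    for name in sorted(_SIM_FIELDS):
        v = getattr(cfg, name)
        if isinstance(v, tuple):
            v = list(v)
        doc[name] = v
    if cfg.cells is not None and "path" in cfg.cells.provenance:
        doc["positions_file"] = cfg.cells.provenance["path"]
    return doc


def save_config(path, cfg: SimulationConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def experiment_presets(name: str, **overrides) -> SimulationConfig:
    """Standard experiment setups.

    ``single-cell-glu``
        one isolated cell, 1500 s, bath glutamate set via ``glu_ext``
        (sweep scaffold 0-50 μM).
    ``network-glu``
        100-cell random field (400×400 μm, 20 μm minimum spacing), 1000 s,
        bath glutamate stimulus.
    ``network-abeta``
        same network, no glutamate; the amyloid-β pore is modeled as a
        fractional increase of the calcium leak rate via
        ``abeta_leak_increase``.
    """
    params = working_params()
    if name == "single-cell-glu":
        cfg = SimulationConfig(
            params=params, cells=CellField([[50.0, 50.0]]),
            duration=1500.0, dt=0.005, spacing=2.0, relax_time=2000.0,
        )
    elif name == "network-glu":
        cfg = SimulationConfig(
            params=params, n_cells=100, extent=(400.0, 400.0),
            min_dist=20.0, duration=1000.0, dt=0.005, spacing=2.0,
            relax_time=2000.0,
        )
    elif name == "network-abeta":
        cfg = SimulationConfig(
            params=params, n_cells=100, extent=(400.0, 400.0),
            min_dist=20.0, duration=1000.0, dt=0.005, spacing=2.0,
            relax_time=2000.0, glu_ext=0.0,
        )
    else:
        raise KeyError(
            f"unknown preset {name!r}; expected one of "
            "'single-cell-glu', 'network-glu', 'network-abeta'"
        )
    for key, val in overrides.items():
        if key in _PARAM_FIELDS:
            cfg.params = cfg.params.with_updates(**{key: val})
        elif key in _SIM_FIELDS or key == "cells":
            setattr(cfg, key, val)
        else:
            raise KeyError(f"unknown preset override {key!r}")
    cfg.validate()
    return cfg


@dataclasses.dataclass
class RunManifest:
    config: dict
    seed: object
    version: str
    started: float
    finished: float
    outputs: dict          # filename -> sha256


def write_manifest(out_dir, cfg: SimulationConfig, seed, started: float,
                   files) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    outputs = {}
    for f in files:
        f = Path(f)
        outputs[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    man = RunManifest(config=config_to_dict(cfg), seed=seed,
                      version=__version__, started=started,
                      finished=time.time(), outputs=outputs)
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(man), fh, indent=2, default=float)
    return path
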