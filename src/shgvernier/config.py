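"""YAML/JSON simulation configuration.

A config file has up to three blocks, all optional (missing keys fall back
to package defaults)::

    beam:
      wavelength_um: 0.850
      na_objective: 0.8
      na_condenser: 0.55
      refractive_index: 1.33
      propagation_axis: [0, 0, 1]
    collection:
      na: 0.55
      n_theta: 16
      n_phi: 32
    tissue:
      period_um: 1.9
      filament_length_um: 0.8
      lateral_halfwidth_um: 0.35
      gap_um: 1.6
      n_sarcomeres: 4
      spacing_um: 0.085
      stagger_phase: 0.5
      fluor_target: thick_filament
      separation_axis: [0.0, 0.5, 0.8660254]
"""

from __future__ import annotations

import json
from typing import Optional

import yaml

from . import tissue
from .beam import BeamParameters, derive_beam
from .coherent import CollectionCone

__all__ = [
    "load_config",
    "beam_from_config",
    "cone_from_config",
    "tissue_params_from_config",
]

DEFAULT_BEAM = {
    "wavelength_um": 0.850,
    "na_objective": 0.8,
    "na_condenser": 0.55,
    "refractive_index": 1.33,
    "propagation_axis": (0.0, 0.0, 1.0),
}

DEFAULT_TISSUE = {
    "period_um": tissue.DEFAULT_PERIOD_UM,
    "filament_length_um": tissue.DEFAULT_FILAMENT_LENGTH_UM,
    "lateral_halfwidth_um": tissue.DEFAULT_HALFWIDTH_UM,
    "gap_um": tissue.DEFAULT_GAP_UM,
    "n_sarcomeres": 4,
    "spacing_um": tissue.DEFAULT_SPACING_UM,
    "stagger_phase": 0.5,
    "fluor_target": "thick_filament",
    "separation_axis": tissue.DEFAULT_SEPARATION_AXIS,
}


def load_config(path: Optional[str]) -> dict:
    """Load a YAML or JSON config file; ``None`` yields an empty config."""
    if path is None:
        return {}
    path = str(path)
    with open(path) as fh:
        if path.endswith(".json"):
            cfg = json.load(fh)
        else:
            cfg = yaml.safe_load(fh)
    return cfg or {}


def beam_from_config(cfg: dict) -> BeamParameters:
    params = {**DEFAULT_BEAM, **cfg.get("beam", {})}
    return derive_beam(
        wavelength_um=params["wavelength_um"],
        na_objective=params["na_objective"],
        na_condenser=params["na_condenser"],
        refractive_index=params["refractive_index"],
        propagation_axis=params["propagation_axis"],
    )


def cone_from_config(cfg: dict) -> CollectionCone:
    block = dict(cfg.get("collection", {}))
    block.setdefault("na", {**DEFAULT_BEAM, **cfg.get("beam", {})}["na_condenser"])
    return CollectionCone(
        na=block["na"],
        n_theta=block.get("n_theta", 16),
        n_phi=block.get("n_phi", 32),
    )


def tissue_params_from_config(cfg: dict) -> dict:
    return {**DEFAULT_TISSUE, **cfg.get("tissue", {})}
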