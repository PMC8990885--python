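"""Structured-text (YAML) run configuration.

A run file has sections ``beam``, ``phantom``, ``physics``, ``scoring`` and
``rng``; every physics toggle of the engine is exposed. Example::

    beam:
      species: 12C
      energy: 200.0        # MeV/u
      n_primaries: 10000
      sigma_mm: 0.0
      energy_spread: 0.0
    phantom:
      kind: water          # or: mhd with `density_file`
      dims_cm: [10, 10, 40]
      voxel_mm: [5.0, 5.0, 0.5]
    physics:
      nuclear: true
      straggling: true
      elastic_fraction: 0.25
      secondary_fragmentation: off
      f_mcs: {12C: 1.37}
    scoring:
      dose_file: dose.mhd
    rng:
      seed: 20220325
"""
from __future__ import annotations

import yaml

from .em import EMConfig
from .engine import BeamSpec, TransportConfig, run
from .errors import ConfigurationError
from .materials import WATER, VoxelGrid, make_water_phantom
from .mhdio import read_mhd

__all__ = ["load_config", "build_run", "run_from_config"]


def load_config(path: str) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ConfigurationError("run configuration must be a mapping")
    return cfg


def _build_phantom(sec: dict) -> VoxelGrid:
    kind = sec.get("kind", "water")
    if kind == "water":
        return make_water_phantom(tuple(sec.get("dims_cm", (10, 10, 40))),
                                  tuple(sec.get("voxel_mm", (0.5, 0.5, 0.5))))
    if kind == "mhd":
        rho, spacing_mm, origin_mm = read_mhd(sec["density_file"])
        grid = VoxelGrid(origin=origin_mm / 10.0, voxel_size=spacing_mm / 10.0,
                         shape=rho.shape, materials=[WATER],
                         density=rho.astype(float))
        return grid
    raise ConfigurationError(f"unknown phantom kind {kind!r}")


def build_run(cfg: dict):
    """Validate a config dict and build (BeamSpec, VoxelGrid, TransportConfig)."""
    beam_sec = dict(cfg.get("beam", {}))
    phys = dict(cfg.get("physics", {}))
    rng_sec = dict(cfg.get("rng", {}))
    em = EMConfig(
        f_mcs=dict(phys.get("f_mcs", {})),
        straggling=bool(phys.get("straggling", True)),
        max_frac_eloss=float(phys.get("max_frac_eloss", 0.02)),
        cutoff_mev_u=float(phys.get("cutoff_mev_u", 0.5)),
    )
    tcfg = TransportConfig(
        em=em,
        nuclear=bool(phys.get("nuclear", True)),
        elastic_fraction=float(phys.get("elastic_fraction", 0.25)),
        secondary_fragmentation=str(phys.get("secondary_fragmentation", "off")),
        n_batches=int(phys.get("n_batches", 10)),
    )
    beam = BeamSpec(
        species=str(beam_sec.get("species", "12C")),
        energy=float(beam_sec.get("energy", 200.0)),
        position=tuple(beam_sec.get("position", (0.0, 0.0, 0.0))),
        direction=tuple(beam_sec.get("direction", (0.0, 0.0, 1.0))),
        sigma_mm=float(beam_sec.get("sigma_mm", 0.0)),
        energy_spread=float(beam_sec.get("energy_spread", 0.0)),
        n_primaries=int(beam_sec.get("n_primaries", 1000)),
        seed=int(rng_sec.get("seed", 20220325)),
    )
    grid = _build_phantom(dict(cfg.get("phantom", {})))
    return beam, grid, tcfg


def run_from_config(path: str):
    """Load, build and execute a run; returns (DoseGrid, RunSummary, cfg)."""
    cfg = load_config(path)
    beam, grid, tcfg = build_run(cfg)
    dose, summary = run(beam, grid, tcfg)
    return dose, summary, cfg
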