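"""Structured-text (TOML) run configuration.

Sections: [geometry], [cells], [coupling], [ou], [protocol], [run].
Every field has a default matching the wild-type study conditions, so a
minimal config file is valid.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field

import numpy as np

from .cell import CellParameters, DEFAULT_RANDOM_RANGES, randomize_population
from .engine import substreams
from .inputs import OUParams, ProtocolSchedule, build_protocol, \
    build_stimulus_mask
from .network import GapJunctionNetwork, LatticeGeometry, build_connectivity

__all__ = ["SimulationConfig", "load_config", "dump_config",
           "build_experiment"]


@dataclass
class SimulationConfig:
    # [geometry]
    dims: tuple[int, int, int] = (10, 10, 2)
    spacing_um: float = 40.0
    # [cells]
    ranges: dict = field(default_factory=lambda: {
        k: list(v) for k, v in DEFAULT_RANDOM_RANGES.items()})
    overrides: dict = field(default_factory=dict)  # fixed parameter values
    gapless: bool = False
    extra_leak: float = 0.003
    # [coupling]
    radius: float = 3.0
    mean_degree: float = 8.0
    gc_mean: float = 0.04
    jitter: float = 0.10
    # [ou]
    ou_enabled: bool = True
    mu: float = -0.6
    sigma: float = 0.6
    tau: float = 20.0
    alpha: float = 0.10
    delta: float = 1.0
    ou_compartment: str = "soma"
    # [protocol]
    protocol_kind: str | None = None
    protocol_params: dict = field(default_factory=dict)
    mask_radius: float = 3.0
    mask_fraction: float = 0.4
    g_peak: float = 0.15
    # [run]
    T: float = 10000.0
    dt: float = 0.025
    rec_dt: float = 1.0
    seed: int = 0


_SECTIONS = {
    "geometry": ("dims", "spacing_um"),
    "cells": ("ranges", "overrides", "gapless", "extra_leak"),
    "coupling": ("radius", "mean_degree", "gc_mean", "jitter"),
    "ou": ("ou_enabled", "mu", "sigma", "tau", "alpha", "delta",
           "ou_compartment"),
    "protocol": ("protocol_kind", "protocol_params", "mask_radius",
                 "mask_fraction", "g_peak"),
    "run": ("T", "dt", "rec_dt", "seed"),
}


def load_config(path) -> SimulationConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = SimulationConfig()
    for section, keys in _SECTIONS.items():
        data = raw.get(section, {})
        for k, v in data.items():
            if k not in keys:
                raise ValueError(f"unknown key {k!r} in [{section}]")
            if k == "dims":
                v = tuple(int(x) for x in v)
            setattr(cfg, k, v)
    return cfg


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    if isinstance(v, dict):
        return ("{" + ", ".join(f"{k} = {_toml_value(x)}"
                                for k, x in v.items()) + "}")
    raise TypeError(f"cannot serialize {type(v)}")


def dump_config(cfg: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        for section, keys in _SECTIONS.items():
            fh.write(f"[{section}]\n")
            for k in keys:
                v = getattr(cfg, k)
                if v is None:
                    continue
                fh.write(f"{k} = {_toml_value(v)}\n")
            fh.write("\n")


def build_experiment(cfg: SimulationConfig):
    """Materialize (cells, network, ou, protocol, mask, run_kwargs)."""
    geometry = LatticeGeometry(dims=cfg.dims, spacing_um=cfg.spacing_um)
    ss = substreams(cfg.seed)
    base = CellParameters(**cfg.overrides)
    if cfg.gapless:
        base = base.with_extra_leak(cfg.extra_leak)
    ranges = {k: tuple(v) for k, v in cfg.ranges.items()}
    cells = randomize_population(geometry.n_cells, ranges=ranges,
                                 seed=ss["cells"], base=base)
    if cfg.gapless:
        network = GapJunctionNetwork(
            np.zeros((geometry.n_cells, geometry.n_cells)), gc_mean=0.0)
    else:
        network = build_connectivity(geometry, radius=cfg.radius,
                                     mean_degree=cfg.mean_degree,
                                     gc_mean=cfg.gc_mean, jitter=cfg.jitter,
                                     seed=ss["connectivity"])
    ou = OUParams(mu=cfg.mu, sigma=cfg.sigma, tau=cfg.tau, alpha=cfg.alpha,
                  delta=cfg.delta) if cfg.ou_enabled else None
    protocol = mask = None
    if cfg.protocol_kind:
        protocol = build_protocol(cfg.protocol_kind, **cfg.protocol_params)
        mask = build_stimulus_mask(geometry, radius=cfg.mask_radius,
                                   fraction=cfg.mask_fraction,
                                   seed=ss["mask"])
    run_kwargs = dict(T=cfg.T, dt=cfg.dt, rec_dt=cfg.rec_dt, seed=cfg.seed,
                      g_peak=cfg.g_peak, ou_compartment=cfg.ou_compartment)
    return cells, network, ou, protocol, mask, run_kwargs
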