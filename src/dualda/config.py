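"""Run configuration: YAML-compatible key-value files with a strict schema.

Sections and keys are validated against the schema below; unknown keys are
rejected by name so typos fail loudly rather than silently falling back to
defaults.  All rates are SI-consistent (seconds, metres, mmol), matching
:class:`dualda.ecosystem.BgcParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from typing import Optional

import numpy as np
import yaml

from .ecosystem import BgcParams, ColumnGrid, ColumnModel
from .fourdvar import MinimizerConfig
from .twin import TwinConfig

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """A configuration file violated the schema."""


_GRID_KEYS = {"n_layers", "dz", "kappa", "dt"}
_FORCING_KEYS = {"surface_irradiance"}
_ASSIM_KEYS = {"n_outer", "n_inner", "cg_tol", "precondition", "window",
               "sigma_b_rel", "sigma_b_floor"}
_TWIN_KEYS = {"window", "perturbation_scale", "dense_quantity", "noise_std",
              "mask_fraction", "dense_stride", "sigma_b_rel", "sigma_b_floor",
              "seed"}
_PARAM_KEYS = {f.name for f in dc_fields(BgcParams)}
_TOP_KEYS = {"grid", "params", "forcing", "assimilation", "twin", "seed"}


@dataclass
class RunConfig:
    """Validated, merged settings for grid, model, assimilation and twin."""

    grid: dict
    params: dict
    forcing: dict
    assimilation: dict
    twin: dict
    seed: int = 0

    def build_grid(self) -> ColumnGrid:
        g = dict(self.grid)
        n = int(g.pop("n_layers", 5))
        dz = g.pop("dz", 5.0)
        kappa = g.pop("kappa", 1e-4)
        dt = float(g.pop("dt", 3600.0))
        if np.ndim(dz) == 0:
            return ColumnGrid.uniform(n, float(dz), float(kappa), dt)
        dz = np.asarray(dz, float)
        return ColumnGrid(dz, np.broadcast_to(
            np.atleast_1d(np.asarray(kappa, float)), (dz.size - 1,)
        ).copy(), dt)

    def build_params(self) -> BgcParams:
        return BgcParams(**self.params)

    def build_model(self, use_hand_adjoints: bool = True) -> ColumnModel:
        return ColumnModel(
            self.build_params(),
            self.build_grid(),
            surface_irradiance=self.forcing.get("surface_irradiance", 150.0),
            use_hand_adjoints=use_hand_adjoints,
        )

    def build_minimizer(self) -> MinimizerConfig:
        a = {k: v for k, v in self.assimilation.items()
             if k in ("n_outer", "n_inner", "cg_tol", "precondition")}
        return MinimizerConfig(**a)

    def build_twin(self) -> TwinConfig:
        t = dict(self.twin)
        t.setdefault("seed", self.seed)
        return TwinConfig(**t)

    @property
    def window(self) -> int:
        return int(self.assimilation.get(
            "window", self.twin.get("window", 96)
        ))


def _check_keys(section: str, given: dict, allowed: set) -> None:
    unknown = set(given) - allowed
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigError(
            f"unknown configuration key {section + '.' if section else ''}"
            f"{key!r} (allowed: {', '.join(sorted(allowed))})"
        )


def load_config(path) -> RunConfig:
    """Parse and validate a YAML config file; unknown keys are fatal."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys("", raw, _TOP_KEYS)
    grid = raw.get("grid") or {}
    params = raw.get("params") or {}
    forcing = raw.get("forcing") or {}
    assim = raw.get("assimilation") or {}
    twin = raw.get("twin") or {}
    for name, section, allowed in (
        ("grid", grid, _GRID_KEYS),
        ("params", params, _PARAM_KEYS),
        ("forcing", forcing, _FORCING_KEYS),
        ("assimilation", assim, _ASSIM_KEYS),
        ("twin", twin, _TWIN_KEYS),
    ):
        if not isinstance(section, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        _check_keys(name, section, allowed)
    return RunConfig(
        grid=grid, params=params, forcing=forcing, assimilation=assim,
        twin=twin, seed=int(raw.get("seed", 0)),
    )
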