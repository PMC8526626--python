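"""Strict run configuration: YAML in, fully resolved parameter sets out.

A run config is a nested mapping with optional blocks ``gait``, ``env``,
``sim``, ``classifier``, ``landscape`` and ``ensemble``.  Unknown keys are
rejected (naming the offending key), every default is materialised so output
metadata always carries the complete resolved parameter set.  Angles:
``gait.phi`` is in turns (fraction of a period), classifier thresholds are in
radians — see ``schema()``.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from dataclasses import dataclass, field, fields

import numpy as np
import yaml

from .kinematics import GaitParams
from .friction import EnvironmentParams
from .dynamics import SimConfig
from .metrics import ClassifierConfig
from .landscapes import EnsembleSpec, build_map

__all__ = ["RunConfig", "ConfigError", "load_config", "atomic_write"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def _build(cls, data: dict, block: str):
    if not isinstance(data, dict):
        raise ConfigError(f"config block {block!r} must be a mapping")
    allowed = {f.name for f in fields(cls)}
    for key in data:
        if key not in allowed:
            raise ConfigError(f"unknown config key {block}.{key} (allowed: {sorted(allowed)})")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config block {block!r}: {exc}") from exc


@dataclass(frozen=True)
class EnsembleBlock:
    """Declarative ensemble: either explicit offsets or an evenly spaced span."""

    count: int = 9
    offset_min: float = -0.5
    offset_max: float = 0.5
    offsets: tuple | None = None
    heading: float = 0.0
    start: tuple[float, float] = (0.0, 0.0)

    def resolve_offsets(self) -> tuple:
        if self.offsets is not None:
            return tuple(float(o) for o in self.offsets)
        if self.count < 1:
            raise ConfigError("ensemble.count must be >= 1")
        return tuple(np.linspace(self.offset_min, self.offset_max, self.count))


@dataclass(frozen=True)
class RunConfig:
    """Complete, validated configuration of one CLI invocation."""

    gait: GaitParams = field(default_factory=GaitParams)
    env: EnvironmentParams = field(default_factory=EnvironmentParams)
    sim: SimConfig = field(default_factory=SimConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    ensemble: EnsembleBlock | None = None
    output_dir: str = "."
    verbosity: int = 1

    _TOP_KEYS = {"gait", "env", "sim", "classifier", "landscape", "ensemble", "output_dir", "verbosity"}

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        for key in data:
            if key not in cls._TOP_KEYS:
                raise ConfigError(f"unknown top-level key {key!r} (allowed: {sorted(cls._TOP_KEYS)})")
        gait = _build(GaitParams, data.get("gait", {}), "gait")
        env_data = dict(data.get("env", {}))
        landscape = data.get("landscape")
        fmap = None
        if landscape is not None:
            if not isinstance(landscape, list):
                raise ConfigError("landscape must be a list of primitive specs")
            try:
                fmap = build_map(landscape)
            except (ValueError, TypeError, KeyError) as exc:
                raise ConfigError(f"invalid landscape: {exc}") from exc
        if fmap is not None:
            env_data["friction_map"] = fmap
        env = _build(EnvironmentParams, env_data, "env")
        sim = _build(SimConfig, data.get("sim", {}), "sim")
        classifier = _build(ClassifierConfig, data.get("classifier", {}), "classifier")
        ensemble = None
        if "ensemble" in data:
            ens = dict(data["ensemble"])
            if "offsets" in ens and ens["offsets"] is not None:
                ens["offsets"] = tuple(ens["offsets"])
            if "start" in ens:
                ens["start"] = tuple(ens["start"])
            ensemble = _build(EnsembleBlock, ens, "ensemble")
        return cls(
            gait=gait,
            env=env,
            sim=sim,
            classifier=classifier,
            ensemble=ensemble,
            output_dir=str(data.get("output_dir", ".")),
            verbosity=int(data.get("verbosity", 1)),
        )

    def ensemble_spec(self) -> EnsembleSpec:
        if self.ensemble is None:
            raise ConfigError("config has no 'ensemble' block")
        if self.env.friction_map is None:
            fmap_env = self.env
        else:
            fmap_env = dataclasses.replace(self.env, friction_map=None)
        from .friction import FrictionMap

        return EnsembleSpec(
            offsets=self.ensemble.resolve_offsets(),
            friction_map=self.env.friction_map or FrictionMap(),
            gait=self.gait,
            env=fmap_env,
            sim=self.sim,
            heading=self.ensemble.heading,
            start=self.ensemble.start,
        )

    def metadata(self) -> dict:
        from . import __version__
        from .dynamics import _map_metadata

        env = dataclasses.asdict(self.env)
        env.pop("friction_map", None)
        out = {
            "slithersim_version": __version__,
            "gait": dataclasses.asdict(self.gait),
            "env": env,
            "friction_map": _map_metadata(self.env.friction_map),
            "sim": dataclasses.asdict(self.sim),
            "classifier": dataclasses.asdict(self.classifier),
        }
        if self.ensemble is not None:
            out["ensemble"] = dataclasses.asdict(self.ensemble)
        return out


def load_config(path: str | None) -> RunConfig:
    """Load and validate a YAML run config; ``None`` gives all defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def atomic_write(path: str, writer) -> None:
    """Write a file atomically: ``writer(tmp_path)`` then rename into place."""
    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", suffix=os.path.basename(path))
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def schema() -> str:
    """Human-readable schema of the config format (units and defaults)."""
    return json.dumps(
        {
            "gait": {
                "epsilon": "lateral curvature amplitude (default 7)",
                "k": "lateral wavenumber, waves/body length (default 1)",
                "A": "lifting amplitude (default 0)",
                "phi": "lifting phase offset, in turns [0,1) (default 0)",
                "lam": "lifting/lateral wavenumber ratio (default 1)",
                "lifting_model": "cosine | exp_curvature | none",
            },
            "env": {
                "mu_t_ratio": "transverse/forward friction ratio (default 2)",
                "mu_b_ratio": "backward/forward friction ratio (default 1.5)",
                "froude": "Froude number (default 0.1)",
                "velocity_reg": "Coulomb regularization, body lengths/period (default 1e-6)",
            },
            "sim": {
                "n_periods": "simulated undulation periods (default 10)",
                "n_s": "arclength nodes (default 201)",
                "rtol": "integrator relative tolerance (default 1e-8)",
                "atol": "integrator absolute tolerance (default 1e-10)",
                "samples_per_period": "output samples per period (default 100, min 100)",
                "averaging_window": "trailing metric window, periods (default 1)",
            },
            "classifier": "thresholds in radians / rad-per-period / body-lengths-per-period",
            "landscape": [
                {"type": "disk", "center": "[x, y]", "diameter": "d", "scale": "p"},
                {"type": "strip", "anchor": "[x, y]", "angle": "radians", "width": "w", "scale": "p"},
                {"type": "radial_gradient", "center": "[x, y]", "diameter": "d", "scale": "p", "profile": "linear|quadratic"},
                {"type": "raster", "origin": "[x, y]", "cell_size": "h", "values": "[[...]]"},
            ],
            "ensemble": {
                "count": "number of snakes",
                "offset_min/offset_max": "lateral offset span (body lengths)",
                "offsets": "explicit offset list (overrides span)",
                "heading": "initial mean orientation, radians",
                "start": "[x, y] launch point of the zero-offset snake",
            },
        },
        indent=2,
    )
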