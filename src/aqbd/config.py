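"""Versioned YAML study configuration.

A study config declares everything the pipeline needs up front: the
factors with physical ranges, the response names, the CMA criteria, the
design to generate (CCF or two-level full factorial, with centre
replicates and optional centre overrides), the model-selection alpha, and
the design-space settings (grid, Monte Carlo size, seed, assurance level).

Parsing is fail-fast: unknown keys anywhere in the document are rejected
before any computation, and cross-references (every CMA response must be a
declared response, grid axes must be declared factors) are validated at
load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .design import Factor
from .space import (DEFAULT_N_SIMULATIONS, DEFAULT_SEED, CMASpec, GridAxis,
                    GridSpec)

__all__ = ["StudyConfig", "ConfigError", "load_config"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """The study configuration is malformed or inconsistent."""


def _require_keys(d: dict, allowed: set[str], required: set[str],
                  where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")
    missing = required - set(d)
    if missing:
        raise ConfigError(f"{where}: missing keys {sorted(missing)}")


@dataclass
class StudyConfig:
    """Validated declaration of a method-optimization study."""

    factors: list[Factor]
    responses: list[str]
    response_units: dict[str, str]
    cmas: list[CMASpec]
    design_kind: str = "ccf"                  # "ccf" | "full_factorial"
    n_center: int = 3
    center_override: dict[str, float] = field(default_factory=dict)
    alpha: float = 0.05
    grid: GridSpec | None = None
    n_simulations: int = DEFAULT_N_SIMULATIONS
    seed: int = DEFAULT_SEED
    assurance_level: float = 0.99
    include_residual: bool = True

    def __post_init__(self) -> None:
        if not self.factors:
            raise ConfigError("at least one factor is required")
        if self.design_kind not in ("ccf", "full_factorial"):
            raise ConfigError(f"unknown design kind {self.design_kind!r}")
        declared = set(self.responses)
        for cma in self.cmas:
            if cma.response_name not in declared:
                raise ConfigError(
                    f"CMA references undeclared response "
                    f"{cma.response_name!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")
        if not 0.0 < self.assurance_level < 1.0:
            raise ConfigError("assurance_level must be in (0, 1)")
        fnames = {f.name for f in self.factors}
        if self.grid is not None:
            for ax in self.grid.axes:
                if ax.name not in fnames:
                    raise ConfigError(
                        f"grid axis {ax.name!r} is not a declared factor")
        for name in self.center_override:
            if name not in fnames:
                raise ConfigError(
                    f"center_override names unknown factor {name!r}")

    def default_grid(self) -> GridSpec:
        """Grid over the first two factors, others fixed at their centre."""
        if self.grid is not None:
            return self.grid
        a, b = self.factors[0], self.factors[1]
        fixed = {f.name: f.center for f in self.factors[2:]}
        return GridSpec(axes=(GridAxis(a.name, a.low, a.high),
                              GridAxis(b.name, b.low, b.high)), fixed=fixed)


def _parse_factor(d: dict, where: str) -> Factor:
    _require_keys(d, {"name", "unit", "low", "high"}, {"name", "low", "high"},
                  where)
    return Factor(name=str(d["name"]), low=float(d["low"]),
                  high=float(d["high"]), unit=str(d.get("unit", "")))


def _parse_cma(d: dict, where: str) -> CMASpec:
    _require_keys(d, {"response", "direction", "limit", "target"},
                  {"response", "direction", "limit"}, where)
    target = d.get("target")
    return CMASpec(response_name=str(d["response"]),
                   direction=str(d["direction"]), limit=float(d["limit"]),
                   target=None if target is None else float(target))


def _parse_grid(d: dict) -> GridSpec:
    _require_keys(d, {"axes", "fixed"}, {"axes"}, "modr.grid")
    if len(d["axes"]) != 2:
        raise ConfigError("modr.grid.axes must list exactly 2 axes")
    axes = []
    for i, a in enumerate(d["axes"]):
        _require_keys(a, {"name", "low", "high", "n_points"},
                      {"name", "low", "high"}, f"modr.grid.axes[{i}]")
        axes.append(GridAxis(name=str(a["name"]), low=float(a["low"]),
                             high=float(a["high"]),
                             n_points=int(a.get("n_points", 101))))
    fixed = {str(k): float(v) for k, v in (d.get("fixed") or {}).items()}
    return GridSpec(axes=(axes[0], axes[1]), fixed=fixed)


def config_from_dict(doc: dict) -> StudyConfig:
    _require_keys(doc, {"schema_version", "factors", "responses", "cmas",
                        "design", "model", "modr"},
                  {"schema_version", "factors", "responses", "cmas"},
                  "config")
    if int(doc["schema_version"]) != SCHEMA_VERSION:
        raise ConfigError(
            f"unsupported schema_version {doc['schema_version']!r} "
            f"(expected {SCHEMA_VERSION})")
    factors = [_parse_factor(f, f"factors[{i}]")
               for i, f in enumerate(doc["factors"])]
    responses, units = [], {}
    for i, r in enumerate(doc["responses"]):
        if isinstance(r, str):
            responses.append(r)
            units[r] = ""
        else:
            _require_keys(r, {"name", "unit"}, {"name"}, f"responses[{i}]")
            responses.append(str(r["name"]))
            units[str(r["name"])] = str(r.get("unit", ""))
    cmas = [_parse_cma(c, f"cmas[{i}]") for i, c in enumerate(doc["cmas"])]

    kwargs: dict = {}
    design = doc.get("design") or {}
    _require_keys(design, {"kind", "n_center", "center_override"}, set(),
                  "design")
    if "kind" in design:
        kwargs["design_kind"] = str(design["kind"])
    if "n_center" in design:
        kwargs["n_center"] = int(design["n_center"])
    if "center_override" in design:
        kwargs["center_override"] = {str(k): float(v) for k, v in
                                     (design["center_override"] or {}).items()}
    mdl = doc.get("model") or {}
    _require_keys(mdl, {"alpha"}, set(), "model")
    if "alpha" in mdl:
        kwargs["alpha"] = float(mdl["alpha"])
    modr = doc.get("modr") or {}
    _require_keys(modr, {"grid", "n_simulations", "seed", "assurance_level",
                         "include_residual"}, set(), "modr")
    if "grid" in modr:
        kwargs["grid"] = _parse_grid(modr["grid"])
    if "n_simulations" in modr:
        kwargs["n_simulations"] = int(modr["n_simulations"])
    if "seed" in modr:
        kwargs["seed"] = int(modr["seed"])
    if "assurance_level" in modr:
        kwargs["assurance_level"] = float(modr["assurance_level"])
    if "include_residual" in modr:
        kwargs["include_residual"] = bool(modr["include_residual"])
    return StudyConfig(factors=factors, responses=responses,
                       response_units=units, cmas=cmas, **kwargs)


def load_config(path) -> StudyConfig:
    """Load and validate a YAML study configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    try:
        return config_from_dict(doc)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
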