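"""Configuration, serialization and canned fixtures.

Configs are flat JSON (canonical) or YAML mappings; unknown keys are
rejected and missing keys fall back to the reference parameter values.
All model quantities are dimensionless: time in units of the toxin
lifetime at normal growth, concentration in units of the maximal toxin
production per unit time (for the modelled system that unit corresponds
to roughly 66.7 nM, so 1 nM ~ 0.015).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .equilibrium import InvalidInputError
from .tamodel import TAParams

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "nm_to_dimensionless",
    "fixture_suite",
    "manifest",
]

_PARAM_FIELDS = tuple(f.name for f in dataclasses.fields(TAParams))


class ConfigError(ValueError):
    """Raised on invalid configuration files; message lists all violations."""


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved run configuration."""

    params: TAParams = field(default_factory=TAParams)
    seed: int = 0
    n_samples: int = 1000
    fold_exponents: tuple[int, ...] = (-3, -2, -1, 0, 1, 2, 3)
    ktl_grid: tuple[float, ...] = ()
    kg_grid: tuple[float, ...] = ()
    rel_tol: float = 1e-12
    out_dir: str = "."

    def to_dict(self) -> dict:
        d = {f: getattr(self.params, f) for f in _PARAM_FIELDS}
        d.update(
            seed=self.seed,
            n_samples=self.n_samples,
            fold_exponents=list(self.fold_exponents),
            ktl_grid=list(self.ktl_grid),
            kg_grid=list(self.kg_grid),
            rel_tol=self.rel_tol,
            out_dir=self.out_dir,
        )
        return d


_SCALAR_KEYS = {"seed": int, "n_samples": int, "rel_tol": float, "out_dir": str}
_LIST_KEYS = {"fold_exponents", "ktl_grid", "kg_grid"}


def _build(data: dict, source: str) -> RunConfig:
    problems = []
    known = set(_PARAM_FIELDS) | set(_SCALAR_KEYS) | _LIST_KEYS
    for key in data:
        if key not in known:
            problems.append(f"unknown key {key!r}")
    pkw = {}
    for name in _PARAM_FIELDS:
        if name in data:
            v = data[name]
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                problems.append(f"{name} must be a number, got {v!r}")
            else:
                pkw[name] = int(v) if name == "n" else float(v)
    skw = {}
    for name, typ in _SCALAR_KEYS.items():
        if name in data:
            try:
                skw[name] = typ(data[name])
            except (TypeError, ValueError):
                problems.append(f"{name} must be {typ.__name__}, got {data[name]!r}")
    for name in _LIST_KEYS:
        if name in data:
            v = data[name]
            if not isinstance(v, (list, tuple)):
                problems.append(f"{name} must be a list, got {v!r}")
            else:
                skw[name] = tuple(int(x) if name == "fold_exponents" else float(x) for x in v)
    params = None
    if not problems:
        try:
            params = TAParams(**pkw)
        except InvalidInputError as exc:
            problems.append(str(exc))
    if problems:
        raise ConfigError(f"invalid config {source}: " + "; ".join(problems))
    return RunConfig(params=params, **skw)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON or YAML config; defaults fill missing keys."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text) or {}
    else:
        data = json.loads(text) if text.strip() else {}
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a mapping")
    return _build(data, str(path))


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the fully resolved config as canonical JSON."""
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True) + "\n")


def nm_to_dimensionless(value_nM: float, unit_nM: float) -> float:
    """Convert a nanomolar concentration to model units (value / unit)."""
    if not unit_nM > 0:
        raise InvalidInputError(f"unit_nM must be positive, got {unit_nM!r}")
    if value_nM < 0:
        raise InvalidInputError(f"value_nM must be non-negative, got {value_nM!r}")
    return value_nM / unit_nM


def manifest(cfg: RunConfig, extra: dict | None = None) -> dict:
    """Reproducibility manifest: config hash, seed and package version."""
    from . import __version__

    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    m = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": cfg.seed,
        "taswitch_version": __version__,
    }
    if extra:
        m.update(extra)
    return m


def fixture_suite() -> dict[str, RunConfig]:
    """Canned configurations used by tests and the worked examples.

    * ``reference``: full growth-feedback model at the reference values
      (bistable: growing + dormant states).
    * ``no_feedback``: the same operon with k_tl = k_g = 0 (monostable).
    * ``motif_bistable`` / ``motif_monostable``: one-variable motif points.
    * ``mini_state_diagram``: a 5x5 (k_tl, k_g) grid.
    * ``mini_robustness``: a 50-sample ensemble scan.

    Expected outputs for these configs are frozen in
    ``taswitch/fixtures/expected.json``.
    """
    ref = TAParams()
    grids = tuple(float(x) for x in (1.0, 4.0, 11.0, 44.0, 176.0))
    return {
        "reference": RunConfig(params=ref),
        "no_feedback": RunConfig(params=ref.without_feedback()),
        "motif_bistable": RunConfig(params=ref),  # motif settings in expected.json
        "motif_monostable": RunConfig(params=ref),
        "mini_state_diagram": RunConfig(params=ref, ktl_grid=grids, kg_grid=grids),
        "mini_robustness": RunConfig(params=ref, n_samples=50, seed=1234),
    }


def load_expected() -> dict:
    """Frozen expected outputs for the fixture suite."""
    with resources.files("taswitch").joinpath("fixtures/expected.json").open() as fh:
        return json.load(fh)
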