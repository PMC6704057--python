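"""Run configuration: YAML parsing with model defaults and validation.

An empty config yields the two shipped genotypes (control and wt1d) and
the three built-in protocols; every field can be overridden under the
documented keys.  Validation errors name the offending key path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .model import DEFAULT_GENOTYPES, InvalidParameterError, ParameterSet, U_SWEEP_RANGE

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Configuration problem; the message carries the key path."""


_GENOTYPE_KEYS = {"tau1", "tau2", "K1", "K2", "u"}
_TOP_KEYS = {"genotypes", "protocols", "sweep", "cohort", "enrichment", "seed", "out_dir"}


@dataclass
class RunConfig:
    genotypes: dict[str, ParameterSet]
    protocols: dict[str, dict]
    sweep: dict[str, Any]
    cohort: dict[str, Any]
    enrichment: dict[str, Any]
    seed: int = 0
    out_dir: Path = Path("memflex_out")

    def genotype(self, label: str) -> ParameterSet:
        if label not in self.genotypes:
            raise ConfigError(f"genotypes.{label}: not defined")
        return self.genotypes[label]


def _default_config() -> RunConfig:
    lo, hi = U_SWEEP_RANGE
    return RunConfig(
        genotypes=dict(DEFAULT_GENOTYPES),
        protocols={},
        sweep={"u_min": lo, "u_max": hi, "u_steps": 6},
        cohort={"n": 30, "noise_sd": 5.0, "task_type": "freezing"},
        enrichment={},
        seed=0,
        out_dir=Path("memflex_out"),
    )


def _parse_genotype(label: str, block: dict, base: ParameterSet | None) -> ParameterSet:
    if not isinstance(block, dict):
        raise ConfigError(f"genotypes.{label}: expected a mapping")
    unknown = set(block) - _GENOTYPE_KEYS
    if unknown:
        raise ConfigError(f"genotypes.{label}: unknown key(s) {sorted(unknown)}")
    defaults = base or DEFAULT_GENOTYPES["control"]
    try:
        return ParameterSet(
            tau1=float(block.get("tau1", defaults.tau1)),
            tau2=float(block.get("tau2", defaults.tau2)),
            K1=float(block.get("K1", defaults.K1)),
            K2=float(block.get("K2", defaults.K2)),
            u_nominal=float(block.get("u", defaults.u_nominal)),
            label=label,
        )
    except InvalidParameterError as exc:
        raise ConfigError(f"genotypes.{label}: {exc}") from exc


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run config; ``None`` or empty file -> defaults."""
    cfg = _default_config()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return cfg
    if not isinstance(raw, dict):
        raise ConfigError("top level: expected a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"top level: unknown key(s) {sorted(unknown)}")

    for label, block in (raw.get("genotypes") or {}).items():
        base = cfg.genotypes.get(label)
        cfg.genotypes[label] = _parse_genotype(label, block or {}, base)

    protocols = raw.get("protocols") or {}
    if not isinstance(protocols, dict):
        raise ConfigError("protocols: expected a mapping")
    for name, block in protocols.items():
        if not isinstance(block, dict) or "events" not in block:
            raise ConfigError(f"protocols.{name}: needs an 'events' list")
        cfg.protocols[name] = block

    for section in ("sweep", "cohort", "enrichment"):
        block = raw.get(section)
        if block is not None:
            if not isinstance(block, dict):
                raise ConfigError(f"{section}: expected a mapping")
            getattr(cfg, section).update(block)

    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    if "out_dir" in raw:
        cfg.out_dir = Path(raw["out_dir"])
    return cfg
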