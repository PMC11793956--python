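"""Run configuration: YAML parsing, validation and hashing.

A run config is a nested mapping with namespaces for the simulator, the two
trait processes, the period grid and the pipeline.  Unknown keys anywhere
are rejected so typos fail loudly.  The canonical serialized form is hashed
(sha256, truncated) and embedded in every output artifact together with the
seed, so any table can be traced back to the exact settings that produced it.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .careers import SimulationConfig
from .periods import PeriodGrid
from .traits import CohortProcessParams, DisruptiveProcessParams

__all__ = ["RunConfig", "load_config", "config_hash"]


def _build(cls, mapping: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
    kwargs = dict(mapping)
    if cls is SimulationConfig and "entry_window" in kwargs:
        kwargs["entry_window"] = tuple(kwargs["entry_window"])
    return cls(**kwargs)


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full pipeline run."""

    simulator: SimulationConfig = field(default_factory=SimulationConfig)
    cohort: CohortProcessParams = field(default_factory=CohortProcessParams)
    disruptive: DisruptiveProcessParams = field(default_factory=DisruptiveProcessParams)
    grid: PeriodGrid = field(default_factory=lambda: PeriodGrid(1850, 2000, 5))
    n_cohort_traits: int = 100
    n_disruptive_traits: int = 100
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_cohort_traits < 0 or self.n_disruptive_traits < 0:
            raise ValueError("trait counts must be >= 0")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        allowed = {f.name for f in fields(cls)}
        unknown = set(mapping) - allowed
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs: dict = {}
        for name, sub in (
            ("simulator", SimulationConfig),
            ("cohort", CohortProcessParams),
            ("disruptive", DisruptiveProcessParams),
            ("grid", PeriodGrid),
        ):
            if name in mapping:
                kwargs[name] = _build(sub, mapping[name] or {}, name)
        for name in ("n_cohort_traits", "n_disruptive_traits", "seed", "log_level"):
            if name in mapping:
                kwargs[name] = mapping[name]
        return cls(**kwargs)

    def to_mapping(self) -> dict:
        m = asdict(self)
        m["simulator"]["entry_window"] = list(self.simulator.entry_window)
        return m

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_mapping(), sort_keys=True), encoding="utf-8"
        )

    def with_seed(self, seed: int) -> "RunConfig":
        """Override the run seed (propagates to the simulator namespace)."""
        m = self.to_mapping()
        m["seed"] = seed
        m["simulator"]["seed"] = seed
        return RunConfig.from_mapping(m)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.from_mapping(raw)


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the canonical serialized config (seed included)."""
    canon = yaml.safe_dump(config.to_mapping(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
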