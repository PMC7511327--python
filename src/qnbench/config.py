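"""Run configuration: YAML key-value files with strict validation.

A config file holds a flat mapping of the fields below.  Unknown keys are
rejected (a typo must never silently fall back to a default) and every run
writes its fully-resolved configuration next to its outputs so results can
be reproduced from the emitted file alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .scenarios import BenchmarkConfig
from .simulate import DEFAULT_CEP_GRID, DEFAULT_EFFECT_POOL
from .strategies import STRATEGY_NAMES

__all__ = ["RunConfig", "parse_config", "dump_config"]


@dataclass
class RunConfig:
    """Fully-resolved settings for the CLI commands.

    ``cep``/``batch_level`` are the single-condition knobs used by
    ``simulate``; the ``*_levels`` grids drive ``benchmark`` and ``combine``.
    ``seed`` is mandatory for the Monte-Carlo commands (no wall-clock
    seeding: replicate means must be reproducible).
    """

    n_features: int = 1000
    n_samples: int = 8
    n_batches: int = 2
    n_biological: int = 4
    cep: float = 0.5
    batch_level: float = 0.5
    cep_levels: tuple[float, ...] = DEFAULT_CEP_GRID
    batch_levels: tuple[float, ...] = DEFAULT_CEP_GRID
    effect_pool: tuple[float, ...] = DEFAULT_EFFECT_POOL
    batch_mode: str = "proportional"
    strategies: tuple[str, ...] = tuple(STRATEGY_NAMES)
    n_reps: int = 100
    alpha: float = 0.05
    technical_sd: float = 0.05
    batch_bias_sd: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("cep_levels", "batch_levels", "effect_pool", "strategies"):
            setattr(self, name, tuple(getattr(self, name)))
        for c in (self.cep, self.batch_level, *self.cep_levels, *self.batch_levels):
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"cep/batch levels must lie in [0, 1], got {c}")
        if not self.effect_pool or any(m <= 0 for m in self.effect_pool):
            raise ValueError("effect_pool must be non-empty and positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        unknown = set(self.strategies) - set(STRATEGY_NAMES)
        if unknown:
            raise ValueError(f"unknown strategies {sorted(unknown)}")
        if self.batch_mode not in ("proportional", "uniform"):
            raise ValueError(f"unknown batch_mode {self.batch_mode!r}")
        for name in ("n_features", "n_samples", "n_batches", "n_biological", "n_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_benchmark_config(self) -> BenchmarkConfig:
        if self.seed is None:
            raise ValueError("seed is required for benchmark runs")
        return BenchmarkConfig(
            n_features=self.n_features,
            n_samples=self.n_samples,
            n_batches=self.n_batches,
            cep_levels=self.cep_levels,
            batch_levels=self.batch_levels,
            effect_pool=self.effect_pool,
            batch_mode=self.batch_mode,
            strategies=self.strategies,
            n_reps=self.n_reps,
            alpha=self.alpha,
            seed=self.seed,
        )


def parse_config(path: str | Path | None, **overrides) -> RunConfig:
    """Read a YAML config (flat mapping); unknown keys are an error.

    Keyword ``overrides`` (e.g. a ``--seed`` CLI option) take precedence over
    file values.  ``path=None`` uses pure defaults plus overrides.
    """
    raw: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a key-value mapping")
        raw.update(loaded)
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the fully-resolved config; re-parsing it reproduces ``cfg``."""
    data = asdict(cfg)
    for k, v in data.items():
        if isinstance(v, tuple):
            data[k] = list(v)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
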