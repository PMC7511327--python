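"""Synthetic expression data with known, multiplicative class and batch effects.

The generator emulates a one-class, positive-valued proteomics intensity
matrix (features differ in abundance; samples are exchangeable) onto which
known effects are inserted:

* *class effects* — a fraction ``cep`` (class-effect proportion) of features
  is designated differential; each gets a magnitude m drawn from a fixed
  effect pool, and every class-B sample's value for that feature is multiplied
  by (1 + m).  A magnitude of 0.2 therefore means a 20% increment.
* *batch effects* — inserted the same way, but keyed on the batch factor.
  In the default ``proportional`` mode a fraction ``batch_level`` of features
  is perturbed per non-reference batch, mirroring the class-effect recipe; in
  ``uniform`` mode every feature of each non-reference batch is multiplied by
  (1 + batch_level).

Because the inserted effects are strictly multiplicative, dividing affected
entries by (1 + m) recovers the base matrix (up to floating-point rounding),
and the ground-truth differential set is known for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import DataError, Dataset

__all__ = [
    "SimulationConfig",
    "EffectAssignment",
    "generate_base_matrix",
    "assign_classes_and_batches",
    "insert_class_effects",
    "insert_batch_effects",
    "simulate_dataset",
]

DEFAULT_EFFECT_POOL = (0.2, 0.5, 0.8, 1.0, 2.0)
DEFAULT_CEP_GRID = (0.0, 0.2, 0.5, 0.8)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class SimulationConfig:
    """One simulation condition.

    ``cep`` is the class-effect proportion (fraction of features made truly
    differential between the two classes); ``batch_level`` controls the batch
    effect (a feature fraction in ``proportional`` mode, a fold-change level
    in ``uniform`` mode); ``effect_pool`` is the set of candidate effect
    magnitudes, sampled uniformly per affected feature.
    """

    n_features: int = 1000
    n_samples: int = 8
    cep: float = 0.0
    effect_pool: tuple[float, ...] = DEFAULT_EFFECT_POOL
    batch_level: float = 0.0
    batch_mode: str = "proportional"
    n_batches: int = 2
    seed: int = 0
    n_reps: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.cep <= 1.0:
            raise ValueError(f"cep must lie in [0, 1], got {self.cep}")
        if not 0.0 <= self.batch_level <= 1.0:
            raise ValueError(f"batch_level must lie in [0, 1], got {self.batch_level}")
        if not self.effect_pool or any(m <= 0 for m in self.effect_pool):
            raise ValueError("effect_pool must be non-empty and positive")
        if self.batch_mode not in ("proportional", "uniform"):
            raise ValueError(f"unknown batch_mode {self.batch_mode!r}")
        if self.n_features < 1 or self.n_samples < 1:
            raise ValueError("counts must be >= 1")

    def replicate(self, index: int) -> "SimulationConfig":
        """Config for the i-th Monte-Carlo replicate (distinct seed stream)."""
        return replace(self, seed=self.seed + index)


@dataclass
class EffectAssignment:
    """Ground truth of one simulation: which features carry a class effect,
    at which multiplicative magnitude, in which class."""

    magnitudes: dict[str, float] = field(default_factory=dict)
    affected_class: str = "B"

    @property
    def differential_features(self) -> set[str]:
        return set(self.magnitudes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": list(self.magnitudes),
                "magnitude": list(self.magnitudes.values()),
            }
        )


def generate_base_matrix(
    n_features: int,
    n_samples: int,
    seed: int | np.random.Generator,
    location_mean: float = 7.0,
    location_sd: float = 1.2,
    noise_sd: float = 0.25,
) -> pd.DataFrame:
    """One-class positive intensity matrix, log-normal per feature.

    Feature i gets a location mu_i ~ N(location_mean, location_sd) on the
    natural-log scale (features span orders of magnitude in abundance) and
    samples vary around it with log-scale noise ``noise_sd`` (across-sample
    CV about 25%, typical of label-free proteomic intensities).
    """
    rng = np.random.default_rng(seed)
    mu = rng.normal(location_mean, location_sd, size=n_features)
    log_vals = mu[:, None] + rng.normal(0.0, noise_sd, size=(n_features, n_samples))
    values = np.exp(log_vals)
    features = [f"F{i + 1}" for i in range(n_features)]
    samples = [f"S{j + 1}" for j in range(n_samples)]
    return pd.DataFrame(values, index=features, columns=samples)


def assign_classes_and_batches(
    sample_ids,
    n_batches: int,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Random two-class assignment with balanced batches.

    Samples are split into two equal classes A and B; within each class, half
    of the samples go to each batch (equal blocks for ``n_batches`` > 2).
    Returns a sheet with columns sample_id, class, batch, in input order.
    """
    sample_ids = list(sample_ids)
    n = len(sample_ids)
    if n % 2 != 0:
        raise DataError(f"indivisible: {n} samples cannot form 2 equal classes")
    per_class = n // 2
    if per_class % n_batches != 0:
        raise DataError(
            f"indivisible: class size {per_class} not divisible by {n_batches} batches"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    classes = dict.fromkeys(sample_ids)
    batches = dict.fromkeys(sample_ids)
    block = per_class // n_batches
    for c_idx, cls in enumerate("AB"):
        members = [sample_ids[i] for i in order[c_idx * per_class : (c_idx + 1) * per_class]]
        for j, s in enumerate(members):
            classes[s] = cls
            batches[s] = f"Batch{j // block + 1}"
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "class": [classes[s] for s in sample_ids],
            "batch": [batches[s] for s in sample_ids],
        }
    )


def insert_class_effects(
    ds: Dataset,
    cep: float,
    effect_pool=DEFAULT_EFFECT_POOL,
    rng: int | np.random.Generator = 0,
    affected_class: str = "B",
) -> tuple[Dataset, EffectAssignment]:
    """Multiply ``round(cep * n_features)`` random features by (1 + m) in the
    affected class only; return the modified data and the ground truth."""
    rng = np.random.default_rng(rng)
    if affected_class not in ds.class_levels:
        raise DataError(f"class {affected_class!r} absent from dataset")
    k = _round_half_up(cep * ds.n_features)
    chosen = rng.choice(ds.n_features, size=k, replace=False)
    mags = rng.choice(np.asarray(effect_pool, dtype=float), size=k)
    values = ds.values.copy()
    cols = [s for s, c in ds.classes.items() if c == affected_class]
    arr = values[cols].to_numpy()
    arr[chosen, :] *= (1.0 + mags)[:, None]
    values[cols] = arr
    truth = EffectAssignment(
        magnitudes={ds.feature_ids[i]: float(m) for i, m in zip(chosen, mags)},
        affected_class=affected_class,
    )
    return ds.with_values(values), truth


def insert_batch_effects(
    ds: Dataset,
    batch_level: float,
    effect_pool=DEFAULT_EFFECT_POOL,
    rng: int | np.random.Generator = 0,
    mode: str = "proportional",
) -> Dataset:
    """Insert multiplicative batch effects into every non-reference batch.

    The first batch level (in order of appearance) is the untouched
    reference.  ``proportional`` perturbs ``round(batch_level * n_features)``
    random features per batch with magnitudes from ``effect_pool``;
    ``uniform`` multiplies all features of each non-reference batch by
    (1 + batch_level).
    """
    rng = np.random.default_rng(rng)
    values = ds.values.copy()
    for batch in ds.batch_levels[1:]:
        cols = [s for s, b in ds.batches.items() if b == batch]
        if mode == "uniform":
            values[cols] = values[cols] * (1.0 + batch_level)
        elif mode == "proportional":
            k = _round_half_up(batch_level * ds.n_features)
            chosen = rng.choice(ds.n_features, size=k, replace=False)
            mags = rng.choice(np.asarray(effect_pool, dtype=float), size=k)
            arr = values[cols].to_numpy()
            arr[chosen, :] *= (1.0 + mags)[:, None]
            values[cols] = arr
        else:
            raise ValueError(f"unknown batch mode {mode!r}")
    return ds.with_values(values)


def simulate_dataset(cfg: SimulationConfig) -> tuple[Dataset, EffectAssignment]:
    """Full simulation: base matrix -> class/batch assignment -> class effects
    -> batch effects.  Fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    values = generate_base_matrix(cfg.n_features, cfg.n_samples, rng)
    sheet = assign_classes_and_batches(values.columns, cfg.n_batches, rng)
    ds = Dataset(
        values,
        pd.Series(sheet["class"].to_numpy(), index=values.columns),
        pd.Series(sheet["batch"].to_numpy(), index=values.columns),
    )
    ds, truth = insert_class_effects(ds, cfg.cep, cfg.effect_pool, rng)
    ds = insert_batch_effects(ds, cfg.batch_level, cfg.effect_pool, rng, cfg.batch_mode)
    return ds, truth
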