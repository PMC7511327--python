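"""Benchmark scenarios: the CEP x batch-level grid and the three-phase
dataset-combination (mega-analysis) scenario.

The grid scenario repeatedly simulates data with known class and batch
effects, applies every normalization strategy, and scores feature-selection
precision/recall/F plus the gPCA delta; cell summaries are means over
Monte-Carlo replicates.

The combination scenario models merging datasets that were normalized on
separate occasions.  Three one-class technical batches go through three
phases: *adjustment* (arbitrary class labels assigned per batch, one shared
ground-truth set of differential features inserted), *normalization* (the
pairings Batch1+Batch2 and Batch2+Batch3 are each normalized independently
with every strategy), and *combination* (the two normalized pairings are
merged — Batch2 appears twice, once per normalization context — and the
merged set is evaluated; the pairing of origin serves as the batch factor
for the gPCA delta, since the act of combining is what generates the batch
effect)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import DataError, Dataset, merge_datasets
from .evaluate import (
    MetricsRecord,
    gpca_delta,
    precision_recall_f,
    rank_methods,
    select_features_ratio,
    select_features_ttest,
)
from .simulate import (
    DEFAULT_CEP_GRID,
    DEFAULT_EFFECT_POOL,
    EffectAssignment,
    SimulationConfig,
    generate_base_matrix,
    insert_class_effects,
    simulate_dataset,
)
from .strategies import STRATEGY_NAMES, RatioDataset, normalize

__all__ = [
    "BenchmarkConfig",
    "run_benchmark_grid",
    "summarize_grid",
    "simulate_technical_batches",
    "run_combination_scenario",
    "summarize_ranks",
]


def _derived_seed(*keys: int) -> int:
    """Deterministic child seed (< 2**31) from a tuple of integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


@dataclass
class BenchmarkConfig:
    """Settings for the CEP x batch-level benchmark grid."""

    n_features: int = 1000
    n_samples: int = 8
    n_batches: int = 2
    cep_levels: tuple[float, ...] = DEFAULT_CEP_GRID
    batch_levels: tuple[float, ...] = DEFAULT_CEP_GRID
    effect_pool: tuple[float, ...] = DEFAULT_EFFECT_POOL
    batch_mode: str = "proportional"
    strategies: tuple[str, ...] = STRATEGY_NAMES
    n_reps: int = 100
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.strategies) - set(STRATEGY_NAMES)
        if unknown:
            raise ValueError(f"unknown strategies {sorted(unknown)}")
        for c in list(self.cep_levels) + list(self.batch_levels):
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"levels must lie in [0, 1], got {c}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def _evaluate_strategy(
    ds: Dataset, truth: EffectAssignment, strategy: str, alpha: float
) -> MetricsRecord:
    """Normalize with one strategy, select features, score against truth."""
    result = normalize(ds, strategy)
    if isinstance(result, RatioDataset):
        sel = select_features_ratio(result, alpha)
        delta = gpca_delta(result.values, result.batches)
    else:
        sel = select_features_ttest(result, alpha)
        delta = gpca_delta(result.values, result.batches)
    rec = precision_recall_f(sel.selected, truth.differential_features, ds.n_features)
    rec.gpca_delta = delta
    return rec


def _record(rec: MetricsRecord, **context) -> dict:
    row = dict(context)
    row.update(
        tp=rec.tp,
        fp=rec.fp,
        fn=rec.fn,
        precision=rec.precision,
        recall=rec.recall,
        f_score=rec.f_score,
        gpca_delta=rec.gpca_delta,
    )
    return row


def run_benchmark_grid(cfg: BenchmarkConfig) -> pd.DataFrame:
    """Per-replicate tidy metrics over the (cep, batch_level, strategy) grid.

    Columns: cep, batch_level, strategy, replicate, tp, fp, fn, precision,
    recall, f_score, gpca_delta.  Deterministic given ``cfg.seed``.
    """
    rows: list[dict] = []
    for ci, cep in enumerate(cfg.cep_levels):
        for bi, batch_level in enumerate(cfg.batch_levels):
            for rep in range(cfg.n_reps):
                sim = SimulationConfig(
                    n_features=cfg.n_features,
                    n_samples=cfg.n_samples,
                    cep=cep,
                    effect_pool=cfg.effect_pool,
                    batch_level=batch_level,
                    batch_mode=cfg.batch_mode,
                    n_batches=cfg.n_batches,
                    seed=_derived_seed(cfg.seed, ci, bi, rep),
                )
                ds, truth = simulate_dataset(sim)
                for strategy in cfg.strategies:
                    rec = _evaluate_strategy(ds, truth, strategy, cfg.alpha)
                    rows.append(
                        _record(
                            rec,
                            cep=cep,
                            batch_level=batch_level,
                            strategy=strategy,
                            replicate=rep,
                        )
                    )
    return pd.DataFrame(rows)


def summarize_grid(metrics: pd.DataFrame) -> pd.DataFrame:
    """Replicate means per (cep, batch_level, strategy) cell."""
    return (
        metrics.groupby(["cep", "batch_level", "strategy"], sort=False)[
            ["precision", "recall", "f_score", "gpca_delta"]
        ]
        .mean()
        .reset_index()
    )


def simulate_technical_batches(
    n_features: int = 1000,
    n_biological: int = 4,
    n_batches: int = 3,
    seed: int | np.random.Generator = 0,
    technical_sd: float = 0.05,
    batch_bias_sd: float = 0.1,
) -> list[Dataset]:
    """One-class technical-replicate batches of the same biological samples.

    Emulates a replicate-run benchmark design: ``n_biological`` samples are
    profiled once per batch.  Each batch re-measures the shared biological
    matrix with log-scale technical noise (``technical_sd``, ~5% CV) plus a
    systematic per-batch, per-feature bias (``batch_bias_sd``), the natural
    batch effect that arises between runs.  Sample ids are unique per batch
    (``S1_Batch2`` ...); each batch dataset carries a single batch label and
    a single placeholder class label.
    """
    rng = np.random.default_rng(seed)
    base = generate_base_matrix(n_features, n_biological, rng)
    out: list[Dataset] = []
    for b in range(1, n_batches + 1):
        bias = np.exp(rng.normal(0.0, batch_bias_sd, size=n_features))
        noise = np.exp(
            rng.normal(0.0, technical_sd, size=(n_features, n_biological))
        )
        values = base.to_numpy() * bias[:, None] * noise
        cols = [f"{s}_Batch{b}" for s in base.columns]
        frame = pd.DataFrame(values, index=base.index, columns=cols)
        out.append(
            Dataset(
                frame,
                pd.Series(["one"] * n_biological, index=cols),
                pd.Series([f"Batch{b}"] * n_biological, index=cols),
            )
        )
    return out


def _assign_classes_by_order(ds: Dataset) -> Dataset:
    """Arbitrary class labels within one batch: first half A, second half B."""
    n = ds.n_samples
    if n % 2 != 0:
        raise DataError(f"indivisible: {n} samples cannot form 2 equal classes")
    labels = ["A"] * (n // 2) + ["B"] * (n // 2)
    return Dataset(
        ds.values.copy(),
        pd.Series(labels, index=ds.values.columns),
        ds.batches.copy(),
    )


def _combine_ratio(parts: list[RatioDataset], origins: list[str]) -> RatioDataset:
    """Concatenate ratio matrices; pairs keep their origin as batch label."""
    frames = []
    batches = []
    for rds, origin in zip(parts, origins):
        renamed = rds.values.rename(columns=lambda c: f"{c}__{origin}")
        frames.append(renamed)
        batches.append(pd.Series([origin] * rds.n_pairs, index=renamed.columns))
    return RatioDataset(pd.concat(frames, axis=1), pd.concat(batches))


def run_combination_scenario(
    batches: list[Dataset],
    cep: float = 0.5,
    effect_pool=DEFAULT_EFFECT_POOL,
    alpha: float = 0.05,
    seed: int = 0,
    strategies: tuple[str, ...] = STRATEGY_NAMES,
    n_reps: int = 1,
    return_objects: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, list[dict]]:
    """Three-phase adjustment / normalization / combination benchmark.

    ``batches`` are exactly three one-class Datasets sharing one feature axis
    with disjoint sample ids.  Per replicate: every batch gets arbitrary
    class labels (by within-batch sample order) and one shared draw of
    differential features and magnitudes (the biology is the same in every
    batch); the pairings Ba1Ba2 = Batch1+Batch2 and Ba2Ba3 = Batch2+Batch3
    are normalized independently per strategy; the two normalized pairings
    are then merged (Batch2 twice, suffixed by pairing) and re-evaluated,
    with the pairing of origin as the gPCA batch factor.

    Returns tidy rows: replicate, phase, unit, strategy, plus metrics.
    With ``return_objects=True`` also returns, per replicate, the truth, the
    adjusted per-batch datasets, the per-(strategy, pairing) normalization
    outputs and the combined per-strategy objects, for inspection.
    """
    if len(batches) != 3:
        raise DataError("combination scenario needs exactly 3 batches")
    features = batches[0].feature_ids
    for b in batches[1:]:
        if b.feature_ids != features:
            raise DataError("feature mismatch between batches")
    n_features = len(features)
    rows: list[dict] = []
    objects: list[dict] = []
    for rep in range(n_reps):
        rng = np.random.default_rng(_derived_seed(seed, rep))
        labelled = [_assign_classes_by_order(b) for b in batches]
        # one shared truth: same differential features and magnitudes in
        # every batch, applied to the class-B samples
        k = int(np.floor(cep * n_features + 0.5))
        chosen = rng.choice(n_features, size=k, replace=False)
        mags = rng.choice(np.asarray(effect_pool, dtype=float), size=k)
        truth = EffectAssignment(
            magnitudes={features[i]: float(m) for i, m in zip(chosen, mags)}
        )
        adjusted: list[Dataset] = []
        for ds in labelled:
            values = ds.values.copy()
            b_cols = [s for s, c in ds.classes.items() if c == "B"]
            arr = values[b_cols].to_numpy()
            arr[chosen, :] *= (1.0 + mags)[:, None]
            values[b_cols] = arr
            adjusted.append(ds.with_values(values))

        # adjustment phase: per-batch selection on the raw effect-carrying data
        for ds in adjusted:
            sel = select_features_ttest(ds, alpha)
            rec = precision_recall_f(sel.selected, truth.differential_features, n_features)
            rows.append(
                _record(
                    rec,
                    replicate=rep,
                    phase="adjustment",
                    unit=str(ds.batch_levels[0]),
                    strategy="adjust",
                )
            )

        # normalization phase: the two pairings, each strategy independently
        pairings = {"ba1ba2": (0, 1), "ba2ba3": (1, 2)}
        normalized: dict[tuple[str, str], Dataset | RatioDataset] = {}
        for name, (i, j) in pairings.items():
            merged = merge_datasets([adjusted[i], adjusted[j]])
            for strategy in strategies:
                result = normalize(merged, strategy)
                normalized[(strategy, name)] = result
                if isinstance(result, RatioDataset):
                    sel = select_features_ratio(result, alpha)
                    delta = gpca_delta(result.values, result.batches)
                else:
                    sel = select_features_ttest(result, alpha)
                    delta = gpca_delta(result.values, result.batches)
                rec = precision_recall_f(
                    sel.selected, truth.differential_features, n_features
                )
                rec.gpca_delta = delta
                rows.append(
                    _record(
                        rec,
                        replicate=rep,
                        phase="normalization",
                        unit=name,
                        strategy=strategy,
                    )
                )

        # combination phase: merge the two normalized pairings; Batch2 is
        # present twice, once per normalization context
        combined_objects: dict[str, Dataset | RatioDataset] = {}
        for strategy in strategies:
            a = normalized[(strategy, "ba1ba2")]
            b = normalized[(strategy, "ba2ba3")]
            if isinstance(a, RatioDataset):
                combined_r = _combine_ratio([a, b], ["ba1ba2", "ba2ba3"])
                combined_objects[strategy] = combined_r
                sel = select_features_ratio(combined_r, alpha)
                delta = gpca_delta(combined_r.values, combined_r.batches)
            else:
                combined = merge_datasets([a, b], suffixes=("__ba1ba2", "__ba2ba3"))
                combined_objects[strategy] = combined
                origin = pd.Series(
                    ["ba1ba2"] * a.n_samples + ["ba2ba3"] * b.n_samples,
                    index=combined.values.columns,
                )
                sel = select_features_ttest(combined, alpha)
                delta = gpca_delta(combined.values, origin)
            rec = precision_recall_f(sel.selected, truth.differential_features, n_features)
            rec.gpca_delta = delta
            rows.append(
                _record(
                    rec,
                    replicate=rep,
                    phase="combination",
                    unit="combined",
                    strategy=strategy,
                )
            )
        objects.append(
            {
                "truth": truth,
                "adjusted": adjusted,
                "normalized": normalized,
                "combined": combined_objects,
            }
        )
    df = pd.DataFrame(rows)
    if return_objects:
        return df, objects
    return df


def summarize_ranks(
    means: pd.DataFrame, by: list[str] | None = None
) -> pd.DataFrame:
    """Rank strategies per condition: F-score descending, delta ascending.

    ``means`` must hold one row per (condition, strategy) with columns
    ``strategy``, ``f_score`` and (optionally) ``gpca_delta``; ``by`` names
    the condition columns (default: every column that is not a metric or the
    strategy).  Rank 1 is best; ties share the mean rank, so half-ranks can
    occur.
    """
    metric_cols = {"strategy", "precision", "recall", "f_score", "gpca_delta",
                   "tp", "fp", "fn", "replicate"}
    if by is None:
        by = [c for c in means.columns if c not in metric_cols]
    rows = []
    grouped = means.groupby(by, sort=False) if by else [((), means)]
    for key, grp in grouped:
        if not isinstance(key, tuple):
            key = (key,)
        f_ranks = rank_methods(
            dict(zip(grp["strategy"], grp["f_score"])), higher_is_better=True
        )
        if "gpca_delta" in grp and grp["gpca_delta"].notna().all():
            d_ranks = rank_methods(
                dict(zip(grp["strategy"], grp["gpca_delta"])), higher_is_better=False
            )
        else:
            d_ranks = {s: float("nan") for s in grp["strategy"]}
        for s in grp["strategy"]:
            rows.append(
                dict(zip(by, key))
                | {"strategy": s, "f_rank": f_ranks[s], "delta_rank": d_ranks[s]}
            )
    return pd.DataFrame(rows)
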