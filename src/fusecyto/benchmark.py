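"""Benchmark harnesses: resampling, stratified subsampling, metric sweeps.

The evaluation protocol mirrors the study design this package reproduces:
every annotated dataset is subsampled to a fixed size several times (or
stratified by drawing half of every annotated class), each replicate is
clustered at its annotated class count, and all four external indices are
recorded per run. Aggregates (means per method x metric set, descending
ranks per index) are recomputable from the raw records.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .clustering import fusesom_cluster
from .evaluation import Partition, score_all
from .fusion import DEFAULT_VIEW_METRICS
from .io_config import ExpressionMatrix, RunConfig

INDEX_NAMES = ("ARI", "NMI", "FM", "F")


@dataclass
class BenchmarkResult:
    """Raw per-run records plus aggregation helpers."""

    records: pd.DataFrame

    def aggregate(self) -> pd.DataFrame:
        keys = [c for c in ("dataset", "method", "metric_set") if c in self.records]
        return self.records.groupby(keys, sort=False)[list(INDEX_NAMES)].mean()

    def ranks(self) -> pd.DataFrame:
        agg = self.aggregate()
        return agg.rank(ascending=False, method="min")


def _derive_seed(master_seed: int, repeat: int) -> int:
    return int(np.random.default_rng([master_seed, repeat]).integers(2**31))


def subsample_fixed(
    data: ExpressionMatrix, size: int, n_repeats: int = 5, seed: int = 0
) -> list[ExpressionMatrix]:
    """n_repeats uniform without-replacement subsets of exactly ``size`` cells.

    Per-repeat RNG streams are derived deterministically from the master seed.
    """
    if not 1 <= size <= data.n_cells:
        raise ValueError(f"size must be in [1, {data.n_cells}]")
    out = []
    for rep in range(n_repeats):
        rng = np.random.default_rng(_derive_seed(seed, rep))
        rows = rng.choice(data.n_cells, size=size, replace=False)
        out.append(data.subset(rows))
    return out


def stratified_split(
    data: ExpressionMatrix, fraction: float = 0.5, n_repeats: int = 5, seed: int = 0
) -> list[ExpressionMatrix]:
    """Per repeat, sample ceil(fraction * n_c) cells from every annotated class c."""
    if data.annotations is None:
        raise ValueError("stratified_split requires annotations")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    ann = np.asarray(data.annotations)
    classes, counts = np.unique(ann, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every annotated class needs at least 2 cells")
    out = []
    for rep in range(n_repeats):
        rng = np.random.default_rng(_derive_seed(seed, rep))
        rows = []
        for cls, n_c in zip(classes, counts):
            take = int(np.ceil(fraction * n_c))
            idx = np.where(ann == cls)[0]
            rows.append(rng.choice(idx, size=take, replace=False))
        out.append(data.subset(np.sort(np.concatenate(rows))))
    return out


def combination_sweep(
    data: ExpressionMatrix, k: int | None = None, seed: int = 0
) -> BenchmarkResult:
    """Cluster with every nonempty subset of the four default views.

    The SOM is fitted once and shared across all 15 metric-set combinations,
    so differences reflect the view set alone. ``k`` defaults to the number
    of annotated classes.
    """
    if data.annotations is None:
        raise ValueError("combination_sweep requires annotations")
    truth = Partition(labels=np.asarray(data.annotations, dtype=object))
    if k is None:
        k = truth.k
    if k < 2:
        raise ValueError("k must be >= 2")
    base_config = RunConfig(seed=seed)
    shared = fusesom_cluster(data, k=k, config=base_config)
    records = []
    for r in range(1, len(DEFAULT_VIEW_METRICS) + 1):
        for combo in combinations(DEFAULT_VIEW_METRICS, r):
            config = RunConfig(metric_set=list(combo), seed=seed)
            result = fusesom_cluster(data, k=k, config=config, som_model=shared.som)
            scores = score_all(result.partition, truth)
            records.append(
                {"metric_set": "+".join(combo), "k": k, "seed": seed, **scores}
            )
    return BenchmarkResult(records=pd.DataFrame.from_records(records))


def run_benchmark(
    datasets: dict[str, ExpressionMatrix],
    methods: dict | None = None,
    config: RunConfig | None = None,
    stratified: bool = False,
) -> BenchmarkResult:
    """Subsample/stratify each dataset, cluster every replicate, score it.

    ``methods`` maps a method name to a callable
    ``(ExpressionMatrix, k, seed) -> Partition``; the default runs the fused
    pipeline. Third-party clusterers plug in through the same adapter. Each
    replicate is clustered at its own annotated class count. Failures are
    recorded per run, not fatal.
    """
    config = config or RunConfig()
    if methods is None:
        methods = {
            "fusesom": lambda d, k, s: fusesom_cluster(
                d, k, RunConfig(**{**config.__dict__, "seed": s})
            ).partition
        }
    records = []
    for ds_name, data in datasets.items():
        if data.annotations is None:
            raise ValueError(f"dataset {ds_name!r} lacks annotations")
        if stratified:
            replicates = stratified_split(
                data, n_repeats=config.n_repeats, seed=config.seed
            )
        else:
            size = min(config.subsample_size, data.n_cells)
            replicates = subsample_fixed(
                data, size, n_repeats=config.n_repeats, seed=config.seed
            )
        for rep, sub in enumerate(replicates):
            truth = Partition(labels=np.asarray(sub.annotations, dtype=object))
            rep_seed = _derive_seed(config.seed, rep)
            for method_name, fn in methods.items():
                rec = {
                    "dataset": ds_name,
                    "method": method_name,
                    "repeat": rep,
                    "seed": rep_seed,
                }
                try:
                    part = fn(sub, truth.k, rep_seed)
                    rec.update(score_all(part, truth))
                except Exception as exc:  # recorded, not fatal
                    rec["error"] = repr(exc)
                records.append(rec)
    return BenchmarkResult(records=pd.DataFrame.from_records(records))
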