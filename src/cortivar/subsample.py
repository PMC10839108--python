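"""Exhaustive subsampling of batches: how mean and SD estimates degrade
with sample size.

For each (farm, batch) cell and each subsample size j, every j-subset of
the cell's pigs (or a seeded Monte-Carlo sample of subsets when the
enumeration would exceed a cap) yields a pair of relative differences

    delta  = (mean_subset - mean_full) / mean_full
    delta' = (sd_subset   - sd_full)   / sd_full

with SDs computed with denominators j-1 and n-1. Per-cell percentiles of
both streams are summarized, then averaged across cells per size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations, islice
from typing import Iterator

import numpy as np
import pandas as pd

from cortivar.cohort import Cohort

__all__ = [
    "SubsampleConfig",
    "SubsampleSummary",
    "enumerate_subsets",
    "relative_differences",
    "percentile_summary",
    "run_study",
]

log = logging.getLogger(__name__)

_CHUNK = 100_000  # subsets vectorized per block


@dataclass(frozen=True)
class SubsampleConfig:
    """Sizes, enumeration limits, and percentile conventions of a study run."""

    sizes: tuple[int, ...] = (5, 10, 15, 20)
    mode: str = "exact"
    max_enumeration: int = 2_000_000
    n_draws: int = 10_000
    seed: int = 0
    percentiles: tuple[float, ...] = (5.0, 50.0, 95.0)

    def __post_init__(self) -> None:
        if self.mode not in ("exact", "monte_carlo"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if any(j < 2 for j in self.sizes):
            raise ValueError("every subsample size must be >= 2")
        if self.mode == "monte_carlo" and self.n_draws < 1:
            raise ValueError("monte_carlo requires n_draws >= 1")
        if sorted(self.percentiles) != list(self.percentiles):
            raise ValueError("percentiles must be sorted ascending")


@dataclass
class SubsampleSummary:
    """Per-(farm, batch, size) percentile rows plus per-size cross-batch means.

    ``per_batch`` columns: farm_id, batch_id, j, n_subsamples, exact, and
    one column per percentile for each statistic (``delta_p5`` etc., values
    in percent). ``per_size`` holds the mean over batches of each
    percentile column (the red-line summary), indexed by j.
    """

    per_batch: pd.DataFrame
    per_size: pd.DataFrame
    config: SubsampleConfig = field(default_factory=SubsampleConfig)


def enumerate_subsets(n: int, j: int) -> Iterator[tuple[int, ...]]:
    """Yield every j-subset of range(n) exactly once, lexicographically."""
    if not 1 <= j <= n:
        raise ValueError(f"need 1 <= j <= n, got j={j}, n={n}")
    return combinations(range(n), j)


def _subset_stats_exact(values: np.ndarray, j: int) -> tuple[np.ndarray, np.ndarray]:
    """Means and sample SDs over all C(n, j) subsets, chunk-vectorized."""
    n = len(values)
    sums, sqs = [], []
    it = enumerate_subsets(n, j)
    while True:
        block = list(islice(it, _CHUNK))
        if not block:
            break
        idx = np.asarray(block, dtype=np.intp)
        sub = values[idx]
        sums.append(sub.sum(axis=1))
        sqs.append((sub**2).sum(axis=1))
    s = np.concatenate(sums)
    q = np.concatenate(sqs)
    means = s / j
    var = np.maximum(q - s**2 / j, 0.0) / (j - 1)
    return means, np.sqrt(var)


def _subset_stats_mc(
    values: np.ndarray, j: int, n_draws: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n = len(values)
    # first j entries of a random permutation per draw = SRSWOR
    keys = rng.random((n_draws, n))
    idx = np.argpartition(keys, j - 1, axis=1)[:, :j]
    sub = values[idx]
    return sub.mean(axis=1), sub.std(axis=1, ddof=1)


def relative_differences(
    values: np.ndarray, j: int, config: SubsampleConfig | None = None
) -> tuple[np.ndarray, np.ndarray, bool]:
    """(delta, delta_prime, exact_flag) for all subsamples of size j.

    Returned as fractions (multiply by 100 for percent). Exact enumeration
    is used when mode is ``exact`` and C(n, j) <= ``max_enumeration``;
    otherwise a seeded Monte-Carlo draw of ``n_draws`` subsets, with a
    logged notice when falling back.
    """
    config = config or SubsampleConfig()
    values = np.asarray(values, dtype=float)
    n = len(values)
    if not 2 <= j <= n:
        raise ValueError(f"need 2 <= j <= n, got j={j}, n={n}")
    mu_n = values.mean()
    sigma_n = values.std(ddof=1)
    if sigma_n == 0:
        raise ValueError("full-sample SD is zero: delta' undefined")

    n_subsets = math.comb(n, j)
    exact = config.mode == "exact" and n_subsets <= config.max_enumeration
    if config.mode == "exact" and not exact:
        log.info(
            "C(%d, %d) = %d exceeds max_enumeration=%d; falling back to "
            "Monte Carlo with %d draws",
            n, j, n_subsets, config.max_enumeration, config.n_draws,
        )
    if exact:
        means, sds = _subset_stats_exact(values, j)
    else:
        rng = np.random.default_rng((config.seed, n, j))
        means, sds = _subset_stats_mc(values, j, config.n_draws, rng)
    return (means - mu_n) / mu_n, (sds - sigma_n) / sigma_n, exact


def percentile_summary(
    delta: np.ndarray, percentiles=(5.0, 50.0, 95.0)
) -> np.ndarray:
    """Percentiles by linear interpolation between order statistics."""
    delta = np.asarray(delta, dtype=float)
    if delta.size == 0:
        raise ValueError("empty stream: no subsamples to summarize")
    return np.percentile(delta, percentiles, method="linear")


def run_study(cohort: Cohort, config: SubsampleConfig | None = None) -> SubsampleSummary:
    """Run the subsample study over every (farm, batch) cell of a cohort.

    Cells smaller than a requested size skip that size with a logged
    notice. Deterministic given the config (Monte-Carlo draws are seeded
    per cell and size).
    """
    config = config or SubsampleConfig()
    rows = []
    for (farm, batch), values in sorted(cohort.cell_values().items()):
        for j in config.sizes:
            if j > len(values):
                log.info("cell (%s, %s) has n=%d < j=%d; skipped", farm, batch, len(values), j)
                continue
            delta, dprime, exact = relative_differences(values, j, config)
            row = {
                "farm_id": farm,
                "batch_id": batch,
                "j": j,
                "n_subsamples": len(delta),
                "exact": exact,
            }
            for stat, arr in (("delta", delta), ("delta_prime", dprime)):
                pcts = percentile_summary(arr, config.percentiles)
                for p, v in zip(config.percentiles, pcts):
                    row[f"{stat}_p{p:g}"] = 100.0 * v
            rows.append(row)
    if not rows:
        raise ValueError("no (cell, size) combination could be evaluated")
    per_batch = pd.DataFrame(rows)
    value_cols = [c for c in per_batch.columns if c.startswith(("delta_", "delta_prime_"))]
    per_size = per_batch.groupby("j")[value_cols].mean()
    return SubsampleSummary(per_batch=per_batch, per_size=per_size, config=config)
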