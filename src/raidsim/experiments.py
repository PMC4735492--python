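"""Replicate batches, parameter sweeps, the MRR regression, and baseline
calibration.

Seeding scheme: each replicate's generator is built from a
``numpy.random.SeedSequence`` whose entropy is the tuple
``(base_seed, cell_index, replicate_index, tag)``, so any single cell of any
sweep is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError
from .interventions import ControlAssignment, build_controls
from .network import SocialNetwork
from .simcore import RunResult, SimulationConfig, run_simulation

__all__ = [
    "BatchResult",
    "SweepResult",
    "replicate_seed",
    "run_batch",
    "sweep",
    "fit_mrr_regression",
    "calibrate_baseline",
    "baseline_grid",
    "SWEEPABLE",
]

# tags keep run, control-placement, and bootstrap streams independent
_TAG_RUN = 0
_TAG_CONTROLS = 1
_TAG_BOOTSTRAP = 2

SWEEPABLE = ("r", "alpha", "saint_count", "devil_count", "placement")

BOOTSTRAP_RESAMPLES = 1000


def replicate_seed(base_seed: int, cell_index: int, replicate_index: int, tag: int = _TAG_RUN):
    """Deterministic, collision-resistant seed for one replicate of one cell."""
    return np.random.SeedSequence((int(base_seed), int(cell_index), int(replicate_index), int(tag)))


def _bootstrap_ci(
    values: np.ndarray, rng: np.random.Generator, resamples: int = BOOTSTRAP_RESAMPLES
) -> tuple[float, float]:
    """Percentile bootstrap 95% CI of the mean."""
    idx = rng.integers(0, values.size, size=(resamples, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class BatchResult:
    """Replicate-level aggregates for one configuration cell."""

    config: SimulationConfig
    replicate_mrrs: np.ndarray
    replicate_generations: np.ndarray
    replicate_converged: np.ndarray
    mean_mrr: float
    ci95: tuple[float, float]
    mean_generations: float
    fraction_converged: float
    cell_index: int = 0
    base_seed: int = 0

    @property
    def replicates(self) -> int:
        return int(self.replicate_mrrs.size)

    @property
    def se_mrr(self) -> float:
        """Standard error of the mean MRR across replicates."""
        if self.replicate_mrrs.size < 2:
            return 0.0
        return float(self.replicate_mrrs.std(ddof=1) / np.sqrt(self.replicate_mrrs.size))

    def to_frame(self, **extra) -> pd.DataFrame:
        """Tidy per-replicate table (one row per replicate)."""
        df = pd.DataFrame(
            {
                "replicate": np.arange(self.replicates),
                "mrr": self.replicate_mrrs,
                "generations": self.replicate_generations,
                "converged": self.replicate_converged,
            }
        )
        df.insert(0, "cell_index", self.cell_index)
        for k, v in extra.items():
            df.insert(0, k, v)
        return df

    def summary(self) -> dict:
        return {
            "mean_mrr": self.mean_mrr,
            "ci95": list(self.ci95),
            "se_mrr": self.se_mrr,
            "mean_generations": self.mean_generations,
            "median_generations": float(np.median(self.replicate_generations)),
            "fraction_converged": self.fraction_converged,
            "replicates": self.replicates,
        }


def run_batch(
    net: SocialNetwork,
    cfg: SimulationConfig,
    leaders: Iterable[int],
    controls: ControlAssignment | None = None,
    replicates: int | None = None,
    base_seed: int = 0,
    cell_index: int = 0,
) -> BatchResult:
    """Run ``replicates`` independent games with fixed network, leaders, and
    controls, varying only the per-replicate seed."""
    replicates = cfg.replicates if replicates is None else int(replicates)
    if replicates < 1:
        raise ParameterError(f"replicates must be >= 1, got {replicates}")
    leaders = sorted(int(v) for v in leaders)
    if controls is not None:
        controls.validate_against(leaders)
    mrrs = np.empty(replicates)
    gens = np.empty(replicates, dtype=np.int64)
    conv = np.empty(replicates, dtype=bool)
    for i in range(replicates):
        res: RunResult = run_simulation(
            net, cfg, leaders, controls, seed=replicate_seed(base_seed, cell_index, i)
        )
        mrrs[i] = res.mrr
        gens[i] = res.generations
        conv[i] = res.converged
    boot_rng = np.random.default_rng(replicate_seed(base_seed, cell_index, 0, _TAG_BOOTSTRAP))
    return BatchResult(
        config=cfg,
        replicate_mrrs=mrrs,
        replicate_generations=gens,
        replicate_converged=conv,
        mean_mrr=float(mrrs.mean()),
        ci95=_bootstrap_ci(mrrs, boot_rng),
        mean_generations=float(gens.mean()),
        fraction_converged=float(conv.mean()),
        cell_index=cell_index,
        base_seed=base_seed,
    )


@dataclass
class SweepResult:
    """One batch per swept value, plus an optional linear fit of mean MRR
    on control count (only meaningful for saint/devil sweeps)."""

    swept_parameter: str
    values: list
    batch_results: list[BatchResult]
    regression: tuple[float, float, float] | None = None

    def mean_mrrs(self) -> np.ndarray:
        return np.array([b.mean_mrr for b in self.batch_results])

    def to_frame(self) -> pd.DataFrame:
        frames = [
            b.to_frame(**{self.swept_parameter: v})
            for v, b in zip(self.values, self.batch_results)
        ]
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> dict:
        out = {
            "swept_parameter": self.swept_parameter,
            "cells": [
                {"value": v, **b.summary()}
                for v, b in zip(self.values, self.batch_results)
            ],
        }
        if self.regression is not None:
            slope, intercept, r2 = self.regression
            out["regression"] = {"slope": slope, "intercept": intercept, "r_squared": r2}
        return out


def _cell_config_and_controls(
    net: SocialNetwork,
    base_cfg: SimulationConfig,
    leaders: Sequence[int],
    parameter: str,
    value,
    cell_index: int,
    base_seed: int,
) -> tuple[SimulationConfig, ControlAssignment]:
    cfg = base_cfg
    if parameter == "r":
        if int(value) < 1:
            raise ConfigurationError(f"invalid r value {value!r}")
        cfg = base_cfg.evolve(r=int(value))
    elif parameter == "alpha":
        if not (0.0 < float(value) <= 1.0):
            raise ConfigurationError(f"invalid alpha value {value!r}")
        cfg = base_cfg.evolve(alpha=float(value))
    elif parameter == "saint_count":
        cfg = base_cfg.evolve(saints=int(value))
    elif parameter == "devil_count":
        cfg = base_cfg.evolve(devils=int(value))
    elif parameter == "placement":
        cfg = base_cfg.evolve(placement=str(value))
    else:
        raise ConfigurationError(
            f"unknown sweep parameter {parameter!r}; expected one of {SWEEPABLE}"
        )
    cfg.validate(net.n)
    ctrl_rng = np.random.default_rng(replicate_seed(base_seed, cell_index, 0, _TAG_CONTROLS))
    controls = build_controls(net, cfg.saints, cfg.devils, cfg.placement, leaders, ctrl_rng)
    return cfg, controls


def sweep(
    net: SocialNetwork,
    base_cfg: SimulationConfig,
    leaders: Iterable[int],
    parameter: str,
    values: Sequence,
    replicates: int | None = None,
    base_seed: int = 0,
) -> SweepResult:
    """Run one batch per parameter value over a shared network and leader set.

    Control placements are drawn once per cell with a deterministic seed,
    then held fixed across that cell's replicates.
    """
    values = list(values)
    if not values:
        raise ConfigurationError("sweep requires at least one value")
    leaders = sorted(int(v) for v in leaders)
    batches: list[BatchResult] = []
    for idx, value in enumerate(values):
        cfg, controls = _cell_config_and_controls(
            net, base_cfg, leaders, parameter, value, idx, base_seed
        )
        batches.append(
            run_batch(net, cfg, leaders, controls, replicates, base_seed, cell_index=idx)
        )
    regression = None
    if parameter in ("saint_count", "devil_count") and len(values) >= 3:
        regression = fit_mrr_regression(
            [float(v) for v in values], [b.mean_mrr for b in batches]
        )
    return SweepResult(parameter, values, batches, regression)


def fit_mrr_regression(
    counts: Sequence[float], mean_mrrs: Sequence[float]
) -> tuple[float, float, float]:
    """Ordinary least squares of mean MRR on control count.

    Returns ``(slope, intercept, r_squared)``; R-squared is the standard
    coefficient of determination (0 for a constant response).
    """
    x = np.asarray(counts, dtype=np.float64)
    y = np.asarray(mean_mrrs, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ParameterError("regression requires at least 3 (count, mean MRR) points")
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx == 0:
        raise ParameterError("regression requires at least two distinct counts")
    slope = float(((x - xbar) * (y - ybar)).sum() / sxx)
    intercept = float(ybar - slope * xbar)
    ss_tot = float(((y - ybar) ** 2).sum())
    if ss_tot == 0.0:
        return slope, intercept, 0.0
    ss_res = float(((y - (intercept + slope * x)) ** 2).sum())
    return slope, intercept, 1.0 - ss_res / ss_tot


def baseline_grid(
    net: SocialNetwork,
    leaders: Iterable[int],
    candidate_n: Sequence[int],
    candidate_m: Sequence[int],
    replicates: int,
    seed: int,
    base_cfg: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Mean baseline MRR (r=1, alpha=1, no controls) for every (n, m) cell."""
    if not candidate_n or not candidate_m:
        raise ParameterError("candidate grids must be nonempty")
    base_cfg = SimulationConfig() if base_cfg is None else base_cfg
    leaders = sorted(int(v) for v in leaders)
    rows = []
    idx = 0
    for n in candidate_n:
        for m in candidate_m:
            cfg = base_cfg.evolve(n=int(n), m=int(m), r=1, alpha=1.0, saints=0, devils=0)
            batch = run_batch(net, cfg, leaders, None, replicates, seed, cell_index=idx)
            rows.append(
                {
                    "n": int(n),
                    "m": int(m),
                    "mean_mrr": batch.mean_mrr,
                    "se_mrr": batch.se_mrr,
                    "mean_generations": batch.mean_generations,
                    "fraction_converged": batch.fraction_converged,
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def select_calibrated(grid: pd.DataFrame) -> tuple[int, int]:
    """Pick the (n, m) whose baseline mean MRR is closest to 1.0.

    Ties broken by smaller ``|n - m|``, then smaller ``n``, then smaller ``m``.
    """
    ranked = sorted(
        grid.itertuples(index=False),
        key=lambda row: (abs(row.mean_mrr - 1.0), abs(row.n - row.m), row.n, row.m),
    )
    best = ranked[0]
    return int(best.n), int(best.m)


def calibrate_baseline(
    net: SocialNetwork,
    leaders: Iterable[int],
    candidate_n: Sequence[int],
    candidate_m: Sequence[int],
    replicates: int,
    seed: int,
    base_cfg: SimulationConfig | None = None,
) -> tuple[int, int]:
    """Grid-search (n, m) so the baseline mean MRR is as close to 1 as possible."""
    grid = baseline_grid(net, leaders, candidate_n, candidate_m, replicates, seed, base_cfg)
    return select_calibrated(grid)
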