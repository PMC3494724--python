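"""Ensemble simulation: many realizations, grid means, residuals, timing.

The coarse-grained parallelism of the method is the embarrassing one:
independent realizations.  Each realization ``i`` draws from its own
counter-derived stream ``f(base_seed, i)``, so the ensemble mean is
reproducible no matter how the realizations are batched or ordered.

The accuracy statistic between two method variants is the *percentage
residual*  ``100 * |mean_a - mean_b| / mean_b``  evaluated per species per
grid time wherever the reference mean ``mean_b`` is at least a floor
(default 0.5 molecules); the timing statistic is the time per update
``T_up = T_t / (l * m)`` with ``l`` realizations and ``m`` average updates
per realization.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .network_model import ReactionNetwork
from .ssa_core import RngStream, SimulationConfig, make_engine, run_trajectory

__all__ = [
    "EnsembleSummary",
    "ResidualReport",
    "trajectory_stream",
    "run_ensemble",
    "merge_summaries",
    "percentage_residuals",
    "time_per_update",
    "convergence_curve",
]

DEFAULT_RESIDUAL_FLOOR = 0.5


@dataclass
class EnsembleSummary:
    """Per-grid-point ensemble statistics of ``num_realizations`` runs.

    ``mean``/``sem`` are (grid x species); ``mean_updates`` is ``m``, the
    average number of firings per realization (the denominator of the
    time-per-update metric).  The raw sums are kept so summaries over
    disjoint seed ranges merge exactly by the weighted-average identity.
    """

    grid: np.ndarray
    species: list[str]
    mean: np.ndarray
    sem: np.ndarray
    num_realizations: int
    mean_updates: float
    wall_time: float
    sum_: np.ndarray
    sumsq: np.ndarray
    total_updates: int

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.mean, columns=self.species)
        df.insert(0, "time", self.grid)
        return df


@dataclass
class ResidualReport:
    """Percentage residuals between two ensemble summaries.

    ``residuals`` is NaN where the reference mean is below the floor;
    ``num_excluded`` counts those points.  The denominator is always the
    *second* (reference) summary, so the report is asymmetric at the scale
    of the mean difference.
    """

    grid: np.ndarray
    species: list[str]
    residuals: np.ndarray
    floor: float
    max_residual: float
    mean_residual: float
    num_excluded: int


def trajectory_stream(base_seed: int, index: int) -> RngStream:
    """Independent, order-insensitive stream for realization ``index``."""
    return RngStream(
        np.random.default_rng(
            np.random.SeedSequence(entropy=base_seed, spawn_key=(index,))
        )
    )


def run_ensemble(
    network: ReactionNetwork,
    config: SimulationConfig,
    num_realizations: int,
    base_seed: int = 0,
    method: str = "blocked",
    engine_kwargs: dict | None = None,
    first_index: int = 0,
) -> EnsembleSummary:
    """Average ``num_realizations`` independent realizations on the grid.

    Realizations are executed in index order on one reused engine;
    because every realization owns its counter-derived stream, any other
    execution order or batching yields the same sums.  ``first_index``
    shifts the realization indices, so an ensemble can be split into
    batches over disjoint index ranges and merged back exactly.
    """
    if num_realizations < 1:
        raise ValueError("need at least one realization")
    engine = make_engine(network, method, **(engine_kwargs or {}))
    grid = config.grid()
    n_rec = (
        network.num_species
        if config.recorded_species is None
        else len(config.recorded_species)
    )
    sum_ = np.zeros((grid.shape[0], n_rec))
    sumsq = np.zeros_like(sum_)
    total_updates = 0
    species: list[str] = []
    t0 = time.perf_counter()
    for i in range(first_index, first_index + num_realizations):
        rec = run_trajectory(
            network, config, seed=trajectory_stream(base_seed, i), engine=engine
        )
        sum_ += rec.data
        sumsq += rec.data * rec.data
        total_updates += rec.updates
        species = rec.species
    wall = time.perf_counter() - t0
    return _summarize(grid, species, sum_, sumsq, num_realizations, total_updates, wall)


def _summarize(grid, species, sum_, sumsq, l, total_updates, wall) -> EnsembleSummary:
    mean = sum_ / l
    if l > 1:
        var = np.maximum(sumsq / l - mean * mean, 0.0) * (l / (l - 1))
        sem = np.sqrt(var / l)
    else:
        sem = np.zeros_like(mean)
    return EnsembleSummary(
        grid=grid,
        species=list(species),
        mean=mean,
        sem=sem,
        num_realizations=l,
        mean_updates=total_updates / l,
        wall_time=wall,
        sum_=sum_,
        sumsq=sumsq,
        total_updates=total_updates,
    )


def merge_summaries(a: EnsembleSummary, b: EnsembleSummary) -> EnsembleSummary:
    """Pool two summaries over disjoint seed ranges (weighted-mean identity)."""
    if a.grid.shape != b.grid.shape or not np.allclose(a.grid, b.grid):
        raise ValueError("summaries live on different grids")
    if a.species != b.species:
        raise ValueError("summaries record different species")
    return _summarize(
        a.grid,
        a.species,
        a.sum_ + b.sum_,
        a.sumsq + b.sumsq,
        a.num_realizations + b.num_realizations,
        a.total_updates + b.total_updates,
        a.wall_time + b.wall_time,
    )


def percentage_residuals(
    summary_a: EnsembleSummary,
    summary_b: EnsembleSummary,
    floor: float = DEFAULT_RESIDUAL_FLOOR,
) -> ResidualReport:
    """Percentage residuals of ``summary_a`` against reference ``summary_b``.

    ``residual(t, s) = 100 * |mean_a - mean_b| / mean_b`` wherever
    ``mean_b >= floor``; other points are excluded (and counted).
    """
    if summary_a.grid.shape != summary_b.grid.shape or not np.allclose(
        summary_a.grid, summary_b.grid
    ):
        raise ValueError("summaries live on different grids")
    if summary_a.species != summary_b.species:
        raise ValueError("summaries record different species")
    ref = summary_b.mean
    ok = ref >= floor
    res = np.full(ref.shape, np.nan)
    res[ok] = 100.0 * np.abs(summary_a.mean[ok] - ref[ok]) / ref[ok]
    n_ok = int(ok.sum())
    return ResidualReport(
        grid=summary_a.grid,
        species=list(summary_a.species),
        residuals=res,
        floor=floor,
        max_residual=float(np.nanmax(res)) if n_ok else float("nan"),
        mean_residual=float(np.nanmean(res)) if n_ok else float("nan"),
        num_excluded=int(ok.size - n_ok),
    )


def time_per_update(total_time: float, num_realizations: int, mean_updates: float) -> float:
    """``T_up = T_t / (l * m)`` — reported, never compared across hardware."""
    if num_realizations <= 0 or mean_updates <= 0:
        raise ValueError("time per update needs l > 0 and m > 0")
    return total_time / (num_realizations * mean_updates)


def convergence_curve(
    network: ReactionNetwork,
    config: SimulationConfig,
    l_values,
    method: str = "blocked",
    base_seed: int = 0,
    reference: EnsembleSummary | None = None,
    engine_kwargs: dict | None = None,
):
    """Time-per-update and (optional) residual-vs-reference for growing ``l``.

    Returns a pandas DataFrame with one row per requested realization
    count; timing columns are for plotting only.
    """
    import pandas as pd

    l_values = list(l_values)
    if any(b <= a for a, b in zip(l_values, l_values[1:])):
        raise ValueError("l_values must be strictly ascending")
    rows = []
    for l in l_values:
        summary = run_ensemble(
            network, config, l, base_seed=base_seed, method=method, engine_kwargs=engine_kwargs
        )
        row = {
            "realizations": l,
            "mean_updates": summary.mean_updates,
            "wall_time_s": summary.wall_time,
            "time_per_update_s": time_per_update(
                summary.wall_time, l, summary.mean_updates
            ),
        }
        if reference is not None:
            row["max_residual_pct"] = percentage_residuals(summary, reference).max_residual
        rows.append(row)
    return pd.DataFrame(rows)
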