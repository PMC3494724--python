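"""Single-trajectory exact SSA driver: selection, update, clock, recording.

One step of the exact algorithm draws two uniforms ``z_1, z_2`` in
``(0, 1]`` — in that order, always both — selects the reaction ``r_f`` as
the first whose cumulative propensity reaches ``z_1 * a_R``, advances the
clock by ``dt = ln(1/z_2) / a_R``, and applies the stoichiometry.  The
fixed two-draw contract makes trajectories of the blocked engine and of the
reference Direct/Optimized-Direct engines comparable step for step under a
shared seed.

Species counts are recorded on a uniform time grid by linear interpolation
between the event states bracketing each grid time; when the system runs
out of reactions (``a_R = 0``) before the final time, the last state is
held constant on the remaining grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network_model import ReactionNetwork

__all__ = [
    "SimulationConfig",
    "RngStream",
    "SimulationClock",
    "TrajectoryRecord",
    "time_advance",
    "make_engine",
    "step",
    "run_trajectory",
]


@dataclass(frozen=True)
class SimulationConfig:
    """What to simulate and what to record.

    ``record_dt`` defaults to 0.01 model-time units; ``recorded_species``
    is a tuple of species indices (None records every species).

    ``interpolation`` selects the grid estimator: ``"linear"`` blends the
    two event states bracketing each grid time (the protocol used for
    cross-method residuals), ``"hold"`` records the exact piecewise-
    constant state (the event state in force at the grid time).  Linear
    blending carries a systematic offset of up to one stoichiometric jump
    per species — use ``"hold"`` when comparing against closed forms.
    """

    t_final: float
    record_dt: float = 0.01
    recorded_species: tuple[int, ...] | None = None
    interpolation: str = "linear"

    def __post_init__(self) -> None:
        if self.t_final < 0:
            raise ValueError("t_final must be non-negative")
        if self.record_dt <= 0:
            raise ValueError("record_dt must be positive")
        if self.interpolation not in ("linear", "hold"):
            raise ValueError("interpolation must be 'linear' or 'hold'")

    def grid(self) -> np.ndarray:
        n = int(math.floor(self.t_final / self.record_dt + 1e-9)) + 1
        return np.arange(n) * self.record_dt


class RngStream:
    """Seedable uniform stream delivering exactly two draws per step.

    Draws are mapped from numpy's ``[0, 1)`` to ``(0, 1]`` (``z = 1 - u``)
    so that neither the selection target ``z_1 * a_R`` can be zero nor the
    waiting-time logarithm singular.
    """

    def __init__(self, seed_or_gen) -> None:
        if isinstance(seed_or_gen, np.random.Generator):
            self.generator = seed_or_gen
        else:
            self.generator = np.random.default_rng(seed_or_gen)
        self.draws = 0

    def pair(self) -> tuple[float, float]:
        """The step's ``(z_1, z_2)``, both in (0, 1]."""
        u = self.generator.random(2)
        self.draws += 2
        return 1.0 - u[0], 1.0 - u[1]


@dataclass
class SimulationClock:
    """Non-decreasing simulation time with its final-time bound."""

    t_final: float
    t_sim: float = 0.0

    def advance(self, dt: float) -> None:
        if dt < 0:
            raise ValueError("negative time step")
        self.t_sim += dt

    @property
    def running(self) -> bool:
        return self.t_sim < self.t_final


@dataclass
class TrajectoryRecord:
    """Grid-sampled counts of the recorded species of one realization.

    ``data[g, s]`` is the (real-valued, linearly interpolated) count of
    recorded species ``s`` at grid time ``grid[g]``.  ``updates`` is the
    number of reaction firings the realization executed.
    """

    grid: np.ndarray
    data: np.ndarray
    species: list[str]
    updates: int
    final_time: float
    events: list[tuple[float, int, float]] | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.data, columns=self.species, index=pd.Index(self.grid, name="time"))


def time_advance(a_R: float, z2: float) -> float:
    """Exponential waiting time ``dt = ln(1/z_2) / a_R``."""
    if a_R <= 0:
        raise ValueError("time advance requires a positive total propensity")
    if not 0.0 < z2 <= 1.0:
        raise ValueError("z2 must lie in (0, 1]")
    return math.log(1.0 / z2) / a_R


def make_engine(network: ReactionNetwork, method: str = "blocked", **kwargs):
    """Engine factory: ``method`` is 'blocked', 'odm' or 'direct'."""
    if method == "blocked":
        from .blocked_engine import BlockedEngine

        return BlockedEngine(network, **kwargs)
    if method == "odm":
        from .reference_methods import OdmEngine

        return OdmEngine(network, **kwargs)
    if method == "direct":
        from .reference_methods import DirectEngine

        return DirectEngine(network, **kwargs)
    raise ValueError(f"unknown method {method!r}")


def step(engine, rng: RngStream):
    """Execute one exact-SSA step on ``engine``.

    Returns ``(fired_index, dt)`` or ``None`` when no reaction can fire
    (``a_R = 0``; no draws are consumed in that case).
    """
    a_R = engine.total_propensity
    if a_R <= 0.0:
        return None
    z1, z2 = rng.pair()
    f = engine.select(z1)
    dt = math.log(1.0 / z2) / a_R
    engine.fire(f)
    return f, dt


def run_trajectory(
    network: ReactionNetwork,
    config: SimulationConfig,
    seed=0,
    method: str = "blocked",
    engine=None,
    collect_events: bool = False,
    engine_kwargs: dict | None = None,
) -> TrajectoryRecord:
    """Run one realization until ``t_final`` (or extinction of all channels).

    A pre-built ``engine`` is reset and reused — the fast path for
    ensembles; otherwise one is created for ``method``.
    """
    if engine is None:
        engine = make_engine(network, method, **(engine_kwargs or {}))
    else:
        engine.reset()
    rng = seed if isinstance(seed, RngStream) else RngStream(seed)

    rec_idx = (
        np.arange(network.num_species)
        if config.recorded_species is None
        else np.asarray(config.recorded_species, dtype=np.int64)
    )
    names = [network.species_names[i] for i in rec_idx]
    grid = config.grid()
    n_grid = grid.shape[0]
    out = np.empty((n_grid, rec_idx.shape[0]))
    state = engine.state  # float counts with trailing dummy entry
    out[0] = state[rec_idx]
    events: list[tuple[float, int, float]] | None = [] if collect_events else None

    t = 0.0
    t_final = config.t_final
    gi = 1
    updates = 0
    log = math.log
    while t < t_final:
        a_R = engine.total_propensity
        if a_R <= 0.0:
            break
        z1, z2 = rng.pair()
        f = engine.select(z1)
        dt = log(1.0 / z2) / a_R
        t_next = t + dt
        if gi < n_grid and t_next >= grid[gi]:
            x_prev = state[rec_idx].copy()
            engine.fire(f)
            x_next = state[rec_idx]
            if config.interpolation == "linear":
                while gi < n_grid and grid[gi] <= t_next:
                    frac = (grid[gi] - t) / dt
                    out[gi] = x_prev + (x_next - x_prev) * frac
                    gi += 1
            else:  # zero-order hold: the state in force at the grid time
                while gi < n_grid and grid[gi] <= t_next:
                    out[gi] = x_next if grid[gi] == t_next else x_prev
                    gi += 1
        else:
            engine.fire(f)
        if events is not None:
            events.append((t_next, f, dt))
        t = t_next
        updates += 1
    if gi < n_grid:  # extinction (or t_final == 0): hold the final state
        out[gi:] = state[rec_idx]
    return TrajectoryRecord(grid, out, names, updates, min(t, t_final), events)
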