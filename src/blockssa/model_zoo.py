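"""Benchmark network generators: cyclic chain, colloidal aggregation,
random consistent networks.

All three families default to the benchmark study conditions: every rate
constant 1 and every initial molecular count 1.

* ``cyclic_chain(N)`` — the weakly coupled system: ``s_i -> s_{i+1 mod N}``,
  M = N unimolecular reactions, exactly 2 dependents per reaction.
* ``colloidal_aggregation(N)`` — the strongly coupled system: all
  aggregations ``s_i + s_j -> s_{i+j}`` (i <= j, i+j <= N) plus the
  corresponding fragmentations ``s_{i+j} -> s_i + s_j``; the maximum
  dependent count grows as 3N - 7.
* ``random_network(N, M)`` — random *consistent* networks with per-reaction
  dependent counts confined to a requested window (8-16 by default).
  Consistency here means closed species flow — every species any reaction
  consumes is produced by some reaction — and the construction additionally
  gives every consumed species a unimolecular branching channel, which
  makes a zero-propensity absorbing state unreachable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dependency_graph import build_dependency_graph, connectivity_stats
from .network_model import (
    InvalidModelError,
    ReactionNetwork,
    Species,
    reaction_from_lists,
)

__all__ = [
    "GenerationError",
    "GeneratorSpec",
    "cyclic_chain",
    "colloidal_aggregation",
    "random_network",
]


class GenerationError(RuntimeError):
    """The random generator could not satisfy the requested constraints."""


def _species(N: int, initial_count: int) -> list[Species]:
    return [Species(i, f"s{i + 1}", initial_count) for i in range(N)]


def cyclic_chain(N: int, k: float = 1.0, initial_count: int = 1) -> ReactionNetwork:
    """Cyclic chain of ``N`` unimolecular conversions, M = N reactions."""
    if N < 2:
        raise ValueError("cyclic chain needs N >= 2")
    reactions = [
        reaction_from_lists(i, 1, [i], [(i + 1) % N], k) for i in range(N)
    ]
    return ReactionNetwork(_species(N, initial_count), reactions)


def colloidal_aggregation(N: int, k: float = 1.0, initial_count: int = 1) -> ReactionNetwork:
    """Colloidal aggregation/fragmentation over cluster sizes 1..N.

    Aggregation ``s_i + s_j -> s_{i+j}`` is Type 2 for i < j and Type 3
    for i = j; every product cluster also fragments back by the
    unimolecular reverse channel.  Species ``s_i`` is the cluster of size
    ``i`` (1-based sizes, 0-based indices).
    """
    if N < 3:
        raise ValueError("colloidal aggregation needs N >= 3")
    reactions = []
    idx = 0
    for i in range(1, N + 1):
        for j in range(i, N - i + 1):
            rtype = 3 if i == j else 2
            reactions.append(
                reaction_from_lists(idx, rtype, [i - 1, j - 1], [i + j - 1], k)
            )
            idx += 1
    for size in range(2, N + 1):
        for i in range(1, size // 2 + 1):
            j = size - i
            reactions.append(
                reaction_from_lists(idx, 1, [size - 1], [i - 1, j - 1], k)
            )
            idx += 1
    return ReactionNetwork(_species(N, initial_count), reactions)


def _dependent_counts(network: ReactionNetwork) -> np.ndarray:
    graph = build_dependency_graph(network, block_size=network.num_reactions)
    return connectivity_stats(graph)[0]


def random_network(
    N: int,
    M: int | None = None,
    dependency_range: tuple[int, int] = (8, 16),
    seed: int = 0,
    k: float = 1.0,
    initial_count: int = 1,
    type3_fraction: float = 0.1,
    max_attempts: int = 20,
) -> ReactionNetwork:
    """Random consistent network with dependent counts in ``dependency_range``.

    Two construction modes are chosen from the requested window:

    * a *chain-like* mode (window upper bound < 8): M = N unimolecular
      conversions along a random cycle over all species — every reaction
      has exactly 2 dependents;
    * a *bimolecular* mode (default): branching, coalescence, conversion
      and dimerization channels (see :func:`_random_bimolecular`) over an
      *active* subset of species sized so every active species is consumed
      by exactly ``g`` reactions.  With about three species changed per
      firing and a balanced consumer degree ``g``, per-reaction dependent
      counts concentrate near ``3g - 1``; a local product-repair pass pins
      every count inside the window.  Species outside the active subset
      take part in no reaction and stay frozen at their initial count.

    The result is reproducible: a fixed ``seed`` yields an identical
    network.
    """
    if M is None:
        M = N
    lo, hi = dependency_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid dependency range")
    if hi < 8:
        if not lo <= 2 <= hi:
            raise GenerationError(
                "chain-like mode yields exactly 2 dependents per reaction; "
                f"requested range [{lo}, {hi}] excludes it"
            )
        return _random_chain_like(N, seed, k, initial_count)

    # most channels change three species, so dependent counts concentrate
    # near 3g - 1 for balanced consumer degree g
    g = max(2, int(round(((lo + hi) / 2 + 1) / 3.0)))
    last_err: Exception | None = None
    for attempt in range(max_attempts):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(attempt,))
        )
        try:
            return _random_bimolecular(
                N, M, (lo, hi), g, type3_fraction, rng, k, initial_count
            )
        except GenerationError as err:
            last_err = err
    raise GenerationError(
        f"could not build a network with dependents in [{lo}, {hi}] "
        f"after {max_attempts} attempts: {last_err}"
    )


def _random_chain_like(N: int, seed: int, k: float, initial_count: int) -> ReactionNetwork:
    if N < 2:
        raise ValueError("need N >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    cycle = rng.permutation(N)
    succ = np.empty(N, dtype=np.int64)
    succ[cycle] = np.roll(cycle, -1)
    reactions = [
        reaction_from_lists(i, 1, [i], [int(succ[i])], k) for i in range(N)
    ]
    return ReactionNetwork(_species(N, initial_count), reactions)


def _random_bimolecular(
    N: int,
    M: int,
    window: tuple[int, int],
    g: int,
    type3_fraction: float,
    rng: np.random.Generator,
    k: float,
    initial_count: int,
) -> ReactionNetwork:
    """Persistent random network with balanced consumer degree ``g``.

    Channel shapes: one unimolecular branching ``s_a -> s_b + s_c`` per
    active species (which makes global extinction impossible: any lone
    molecule branches, so the total propensity never reaches zero),
    bimolecular coalescences ``s_a + s_b -> s_c`` sized so branching and
    coalescence balance at a few molecules per active species, plus
    conversions ``s_a + s_b -> s_c + s_d`` and dimerization-conversions
    ``2 s_a -> s_c + s_d`` to fill the degree budget.
    """
    lo, hi = window
    n3 = int(round(type3_fraction * M))
    while (2 * M - n3) % (g + 1):
        n3 += 1
    n_active = (2 * M - n3) // (g + 1)
    if n_active > N:
        raise GenerationError(
            f"need {n_active} active species for consumer degree {g}, have {N}"
        )
    if n_active < 8:
        raise GenerationError("network too small for the bimolecular mode")
    n_uni = n_active
    n_bi = M - n_uni - n3
    n_coal = max(1, n_active // 2)  # 2->1 channels: mean count ~ n_uni/n_coal
    if n_bi < n_coal:
        raise GenerationError("degree budget leaves too few bimolecular channels")
    active = np.sort(rng.choice(N, size=n_active, replace=False))

    # reactant assignment: every active species gets one unimolecular slot
    # and g-1 slots in the bimolecular/dimerization pool
    shapes = (
        ["uni"] * n_uni + ["coal"] * n_coal + ["conv"] * (n_bi - n_coal) + ["dim"] * n3
    )
    order = rng.permutation(M)
    uni_species = rng.permutation(active)
    pool = rng.permutation(np.repeat(active, g - 1))
    reactants: list[list[int]] = []
    rtypes: list[int] = []
    n_products: list[int] = []
    u = p = 0
    for m in range(M):
        shape = shapes[order[m]]
        if shape == "uni":
            reactants.append([int(uni_species[u])])
            rtypes.append(1)
            n_products.append(2)
            u += 1
        elif shape == "dim":
            reactants.append([int(pool[p])] * 2)
            rtypes.append(3)
            n_products.append(2)
            p += 1
        else:
            a = int(pool[p])
            p += 1
            q = p
            while q < pool.shape[0] and pool[q] == a:
                q += 1
            if q == pool.shape[0]:
                raise GenerationError("ran out of distinct reactant slots")
            pool[p], pool[q] = pool[q], pool[p]
            reactants.append([a, int(pool[p])])
            p += 1
            rtypes.append(2)
            n_products.append(1 if shape == "coal" else 2)

    # product slots: every active species once (coverage), rest uniform
    total_products = sum(n_products)
    extra = rng.choice(active, size=total_products - n_active)
    ppool = rng.permutation(np.concatenate([active, extra]))
    products: list[list[int]] = []
    pos = 0
    for m in range(M):
        got: list[int] = []
        forbidden = set(reactants[m])
        for _ in range(n_products[m]):
            q = pos
            while q < ppool.shape[0] and (ppool[q] in forbidden or ppool[q] in got):
                q += 1
            if q == ppool.shape[0]:
                raise GenerationError("ran out of feasible product slots")
            ppool[pos], ppool[q] = ppool[q], ppool[pos]
            got.append(int(ppool[pos]))
            pos += 1
        products.append(got)

    produced = np.zeros(N, dtype=np.int64)
    for ps in products:
        for s in ps:
            produced[s] += 1

    def build() -> ReactionNetwork:
        reactions = [
            reaction_from_lists(m, rtypes[m], reactants[m], products[m], k)
            for m in range(M)
        ]
        return ReactionNetwork(_species(N, initial_count), reactions)

    # local repair: nudge products of out-of-window reactions
    for _ in range(60):
        counts = _dependent_counts(build())
        bad = np.flatnonzero((counts < lo) | (counts > hi))
        if bad.size == 0:
            return build()
        for m in bad[: max(1, bad.size // 2)]:
            slot = int(rng.integers(len(products[m])))
            old = products[m][slot]
            if produced[old] < 2:
                slot = (slot + 1) % len(products[m])
                old = products[m][slot]
                if produced[old] < 2:
                    continue
            for _try in range(12):
                cand = int(rng.choice(active))
                if cand in reactants[m] or cand in products[m]:
                    continue
                products[m][slot] = cand
                produced[old] -= 1
                produced[cand] += 1
                break
    raise GenerationError("product repair did not converge")


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of a benchmark network."""

    family: str
    N: int
    M: int | None = None
    k: float = 1.0
    initial_count: int = 1
    dependency_range: tuple[int, int] = (8, 16)
    seed: int = 0

    def build(self) -> ReactionNetwork:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.family == "cyclic_chain":
            return cyclic_chain(self.N, self.k, self.initial_count)
        if self.family == "colloidal_aggregation":
            return colloidal_aggregation(self.N, self.k, self.initial_count)
        if self.family == "random":
            return random_network(
                self.N,
                self.M,
                self.dependency_range,
                seed=self.seed,
                k=self.k,
                initial_count=self.initial_count,
            )
        raise ValueError(f"unknown family {self.family!r}")
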