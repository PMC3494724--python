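"""Blocked-partial-sum SSA engine: hierarchical selection + incremental updates.

The reaction list is divided into ``p`` blocks of ``b`` propensities
(``b`` a multiple of the 128-wide chunk size).  The engine maintains the
*cumulative* block sums ``B_0 <= B_1 <= ... <= B_{p-1} = a_R`` through
incremental per-firing updates, and selects the next reaction ``r_f`` with a
three-level search of increasing granularity:

1. block level   — first block whose cumulative sum reaches ``z_1 * a_R``;
2. chunk level   — within that block, first 128-wide chunk whose running
   cumulative reaches the target;
3. reaction level — first propensity inside the chunk whose prefix sum
   reaches the target.

The hardware primitives of the source design (warp ballot / find-first-set,
lane-strided reductions) are realized by their algorithmic contract: "first
index at which a predicate over an array segment holds".  The within-block
running sums are seeded with the cumulative sum of all preceding blocks, so
when the block sums are fresh the whole search reproduces a sequential
linear scan of the propensity vector bit for bit.

After a firing, only the propensities of the fired reaction's dependents
are recomputed; their changes are accumulated into per-block deltas
``delta_i``, prefix-summed, and added to the cumulative block sums — the
update cost is O(#dependents + p) instead of O(M).  Floating-point drift of
the incremental sums is bounded by periodic from-scratch refreshes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dependency_graph import DependencyGraph, build_dependency_graph
from .network_model import InternalConsistencyError, ReactionNetwork

__all__ = [
    "SelectionError",
    "BlockPartition",
    "BlockSums",
    "init_block_sums",
    "first_index_ge",
    "select_block",
    "select_chunk",
    "select_within_chunk",
    "hierarchical_select",
    "BlockedEngine",
]

DEFAULT_CHUNK_SIZE = 128
DEFAULT_LANE_WIDTH = 32
#: default cap on the number of blocks (the thread-per-block sweet spot)
DEFAULT_MAX_BLOCKS = 25
#: mean dependents per (source, block) above which the dense update path is used
DEFAULT_DENSE_UPDATE_THRESHOLD = 32


class SelectionError(ValueError):
    """A selection target is outside the feasible range."""


@dataclass(frozen=True)
class BlockPartition:
    """Geometry of the blocked propensity layout.

    ``num_blocks * block_size >= M``; ``block_size`` is a positive multiple
    of ``chunk_size`` which itself is a multiple of ``lane_width``.
    """

    num_blocks: int
    block_size: int
    chunk_size: int = DEFAULT_CHUNK_SIZE
    lane_width: int = DEFAULT_LANE_WIDTH

    def __post_init__(self) -> None:
        if self.num_blocks < 1 or self.block_size < 1:
            raise ValueError("partition needs at least one block of positive size")
        if self.block_size % self.chunk_size:
            raise ValueError("block_size must be a multiple of chunk_size")
        if self.chunk_size % self.lane_width:
            raise ValueError("chunk_size must be a multiple of lane_width")

    @classmethod
    def for_reactions(
        cls,
        num_reactions: int,
        num_blocks: int | None = None,
        block_size: int | None = None,
        chunk_size: int = DEFAULT_CHUNK_SIZE,
        lane_width: int = DEFAULT_LANE_WIDTH,
        max_blocks: int = DEFAULT_MAX_BLOCKS,
    ) -> "BlockPartition":
        """Partition covering ``num_reactions`` propensities.

        By default the block size is the smallest multiple of ``chunk_size``
        that keeps the block count at or below ``max_blocks``.
        """
        if num_reactions < 1:
            raise ValueError("need at least one reaction")
        if block_size is None:
            if num_blocks is None:
                per = -(-num_reactions // max_blocks)
                block_size = -(-per // chunk_size) * chunk_size
            else:
                per = -(-num_reactions // num_blocks)
                block_size = -(-per // chunk_size) * chunk_size
        p = -(-num_reactions // block_size)
        return cls(p, block_size, chunk_size, lane_width)

    def block_range(self, block: int, num_reactions: int) -> tuple[int, int]:
        if not 0 <= block < self.num_blocks:
            raise IndexError(f"block {block} out of range [0, {self.num_blocks})")
        lo = block * self.block_size
        return lo, min(lo + self.block_size, num_reactions)

    def covers(self, num_reactions: int) -> bool:
        return self.num_blocks * self.block_size >= num_reactions


@dataclass
class BlockSums:
    """Cumulative block partial sums; the last entry is the total ``a_R``."""

    cumulative: np.ndarray

    @property
    def total(self) -> float:
        return float(self.cumulative[-1])


def init_block_sums(propensities: np.ndarray, partition: BlockPartition) -> BlockSums:
    """From-scratch cumulative block sums.

    The checkpoints are taken from one sequential cumulative sum of the
    whole vector, so they agree bit for bit with a left-to-right linear
    accumulation.
    """
    a = np.asarray(propensities, dtype=np.float64)
    M = a.shape[0]
    if M == 0:
        raise ValueError("empty propensity vector")
    if not partition.covers(M):
        raise ValueError("partition does not cover the propensity vector")
    cum = np.cumsum(a)
    ends = np.minimum(
        (np.arange(partition.num_blocks) + 1) * partition.block_size, M
    )
    return BlockSums(cum[ends - 1].copy())


def first_index_ge(values: np.ndarray, target: float) -> int:
    """Smallest index whose value reaches ``target``; -1 if none does.

    This is the serial realization of the warp ballot + find-first-set
    primitive pair of the source design.
    """
    mask = values >= target
    i = int(np.argmax(mask))
    if not mask[i]:
        return -1
    return i


def select_block(block_sums: BlockSums, target: float) -> int:
    """First block whose cumulative sum reaches ``target`` (= z_1 * a_R)."""
    if not 0.0 < target <= block_sums.total:
        raise SelectionError(f"target {target} outside (0, {block_sums.total}]")
    return first_index_ge(block_sums.cumulative, target)


def _chunk_ends(length: int, chunk_size: int) -> np.ndarray:
    """End positions (1-based within a block) of each chunk of the block."""
    n = -(-length // chunk_size)
    return np.minimum((np.arange(n) + 1) * chunk_size, length)


def select_chunk(
    propensities: np.ndarray, partition: BlockPartition, block: int, residual: float
) -> tuple[int, float]:
    """First chunk of ``block`` whose running cumulative reaches ``residual``.

    ``residual`` is the selection target minus the cumulative sum of all
    preceding blocks.  Returns the chunk index and the cumulative base of
    that chunk (the summed propensities of the chunks before it).
    """
    a = np.asarray(propensities, dtype=np.float64)
    lo, hi = partition.block_range(block, a.shape[0])
    cum = np.cumsum(a[lo:hi])
    ends = _chunk_ends(hi - lo, partition.chunk_size)
    chunk_cum = cum[ends - 1]
    m = first_index_ge(chunk_cum, residual)
    if m < 0:
        raise SelectionError(f"residual {residual} exceeds block {block} sum")
    base = 0.0 if m == 0 else float(chunk_cum[m - 1])
    return m, base


def select_within_chunk(
    propensities: np.ndarray,
    partition: BlockPartition,
    block: int,
    chunk: int,
    residual: float,
) -> int:
    """Global index of the first in-chunk propensity whose prefix sum
    reaches ``residual`` (the target minus everything before the chunk)."""
    a = np.asarray(propensities, dtype=np.float64)
    lo, hi = partition.block_range(block, a.shape[0])
    j0 = lo + chunk * partition.chunk_size
    j1 = min(j0 + partition.chunk_size, hi)
    if not j0 < j1:
        raise IndexError(f"chunk {chunk} out of range in block {block}")
    prefix = np.cumsum(a[j0:j1])
    j = first_index_ge(prefix, residual)
    if j < 0:
        raise SelectionError(f"residual {residual} exceeds chunk {chunk} sum")
    return j0 + j


def _scan_block(
    a: np.ndarray,
    partition: BlockPartition,
    block: int,
    base: float,
    target: float,
) -> int:
    """Three-level within-block search in the *continued* cumulative frame.

    The running sum is seeded with ``base`` — the cumulative sum of every
    preceding block — and all predicates compare against the original
    ``target``, so with fresh block sums the composed search matches a
    sequential linear scan exactly, including targets that land on
    prefix-sum boundaries.  Returns -1 when the block cannot reach the
    target (stale incremental sums); the caller then refreshes and retries.
    """
    lo = block * partition.block_size
    hi = min(lo + partition.block_size, a.shape[0])
    cont = np.empty(hi - lo + 1)
    cont[0] = base
    cont[1:] = a[lo:hi]
    cont = np.cumsum(cont)
    ends = _chunk_ends(hi - lo, partition.chunk_size)
    m = first_index_ge(cont[ends], target)
    if m < 0:
        return -1
    j0 = 0 if m == 0 else int(ends[m - 1])
    j = first_index_ge(cont[j0 + 1 : ends[m] + 1], target)
    return lo + j0 + j


def hierarchical_select(
    propensities: np.ndarray,
    partition: BlockPartition,
    z1: float,
    block_sums: BlockSums | None = None,
) -> int:
    """Select the next reaction: identical to the Direct Method's linear
    cumulative-sum search, executed as the three-level blocked search.

    Parameters
    ----------
    propensities : array
        Current propensity vector (length M, non-negative).
    partition : BlockPartition
        Block geometry; must cover the vector.
    z1 : float
        Uniform draw in (0, 1]; the target is ``z1 * a_R``.
    block_sums : BlockSums, optional
        Precomputed cumulative block sums; computed from scratch if omitted.

    Returns
    -------
    int
        Index of the reaction to fire, or -1 when the total propensity is
        zero (no reaction can fire).
    """
    a = np.asarray(propensities, dtype=np.float64)
    if block_sums is None:
        block_sums = init_block_sums(a, partition)
    total = block_sums.total
    if total <= 0.0:
        return -1
    if not 0.0 < z1 <= 1.0:
        raise SelectionError(f"z1 must lie in (0, 1], got {z1}")
    target = z1 * total
    l = first_index_ge(block_sums.cumulative, target)
    base = 0.0 if l == 0 else float(block_sums.cumulative[l - 1])
    f = _scan_block(a, partition, l, base, target)
    if f < 0:
        raise SelectionError("block sums inconsistent with propensities")
    return f


class BlockedEngine:
    """Mutable blocked simulation state driving one trajectory at a time.

    Parameters
    ----------
    network : ReactionNetwork
    partition : BlockPartition, optional
        Defaults to the smallest 128-multiple block size with at most 25
        blocks.
    graph : DependencyGraph, optional
        Must be built with the partition's block size; built on demand.
    refresh_interval : int or None
        Firings between unconditional from-scratch refreshes of the
        cumulative block sums (None disables).
    rel_tol : float or None
        Relative drift bound on ``a_R``; checked every ``check_interval``
        firings, breach triggers a refresh (None disables).
    dense_update_threshold : float
        Mean dependents per (source reaction, block) above which the dense
        (vectorized scatter-add) update path is chosen over the sparse
        per-block loop.  Both paths are bitwise identical.
    """

    def __init__(
        self,
        network: ReactionNetwork,
        partition: BlockPartition | None = None,
        graph: DependencyGraph | None = None,
        refresh_interval: int | None = 10_000,
        rel_tol: float | None = 1e-9,
        check_interval: int = 1024,
        dense_update_threshold: float = DEFAULT_DENSE_UPDATE_THRESHOLD,
    ):
        self.network = network
        self.arrays = network.arrays
        M = network.num_reactions
        if partition is None:
            partition = BlockPartition.for_reactions(M)
        if not partition.covers(M):
            raise ValueError("partition does not cover the reaction list")
        self.partition = partition
        if graph is None:
            graph = build_dependency_graph(network, partition.block_size)
        elif graph.block_size != partition.block_size:
            raise ValueError("dependency graph block size does not match partition")
        self.graph = graph
        self.refresh_interval = refresh_interval
        self.rel_tol = rel_tol
        self.check_interval = check_interval
        self._dep_block = (graph.dep_indices // partition.block_size).astype(np.int64)
        mean_per_block = graph.dep_ptr[-1] / max(1, M) / partition.num_blocks
        self.dense_updates = mean_per_block > dense_update_threshold
        self._delta_p = np.zeros(partition.num_blocks)
        self._init_counts = network.initial_counts()
        self.reset()

    # -- lifecycle --------------------------------------------------------
    def reset(self) -> None:
        """Restore the initial state and recompute everything from scratch."""
        self.state = self.arrays.state_vector(self._init_counts)
        self.propensities = self.arrays.propensities(self.state)
        self.block_sums = init_block_sums(self.propensities, self.partition)
        self._cum = self.block_sums.cumulative
        self.fires = 0
        self._since_refresh = 0
        self.refresh_count = 0
        self.selection_work = 0
        self.update_work = 0

    def counts(self) -> np.ndarray:
        """Current molecular counts (integer-valued)."""
        return self.state[:-1].astype(np.int64)

    @property
    def total_propensity(self) -> float:
        return float(self._cum[-1])

    # -- selection --------------------------------------------------------
    def select(self, z1: float) -> int:
        """Reaction index for draw ``z1`` in (0, 1]; requires ``a_R > 0``."""
        total = self._cum[-1]
        if total <= 0.0:
            raise SelectionError("no reaction can fire: total propensity is zero")
        target = z1 * total
        f = self._try_select(target)
        if f < 0:
            # incremental sums drifted past the propensities: refresh, retry
            self.refresh()
            target = z1 * self._cum[-1]
            f = self._try_select(target)
            if f < 0:
                raise InternalConsistencyError("selection failed after refresh")
        return f

    def _try_select(self, target: float) -> int:
        cum = self._cum
        l = first_index_ge(cum, target)
        if l < 0:
            return -1
        base = 0.0 if l == 0 else float(cum[l - 1])
        f = _scan_block(self.propensities, self.partition, l, base, target)
        if f >= 0:
            lo, hi = self.partition.block_range(l, self.propensities.shape[0])
            self.selection_work += hi - lo
        return f

    # -- update -----------------------------------------------------------
    def fire(self, f: int) -> None:
        """Apply the firing of reaction ``f``: counts, propensities, sums."""
        idx = self.arrays.sto_idx[f]
        self.state[idx] += self.arrays.sto_delta[f]
        if np.any(self.state[idx] < 0):
            raise InternalConsistencyError(
                f"firing reaction {f} drove a molecular count negative"
            )
        self.update_after_firing(f)
        self.fires += 1
        self._since_refresh += 1
        if self.rel_tol is not None and self.fires % self.check_interval == 0:
            fresh = float(np.cumsum(self.propensities)[-1])
            if abs(self._cum[-1] - fresh) > self.rel_tol * max(abs(fresh), 1e-300):
                self.refresh()
        if self.refresh_interval is not None and self._since_refresh >= self.refresh_interval:
            self.refresh()

    def update_after_firing(self, f: int) -> None:
        """Recompute dependent propensities; add prefixed per-block deltas
        to the cumulative block sums."""
        graph = self.graph
        s, e = graph.dep_ptr[f], graph.dep_ptr[f + 1]
        idx = graph.dep_indices[s:e]
        old = self.propensities[idx]
        new = self.arrays.propensities(self.state, idx)
        if np.any(new < 0):
            raise InternalConsistencyError("negative propensity after update")
        self.propensities[idx] = new
        d = new - old
        delta_p = self._delta_p
        delta_p[:] = 0.0
        if self.dense_updates:
            # whole-warp path: one scatter-add over the block ids of the deps
            np.add.at(delta_p, self._dep_block[s:e], d)
        else:
            # thread-per-block path: walk the block-sorted segments
            offs = graph.block_offsets[f]
            lo = 0
            for b in range(offs.shape[0]):
                hi = offs[b]
                acc = 0.0
                for j in range(lo, hi):
                    acc += d[j]
                if lo != hi:
                    delta_p[b] = acc
                lo = hi
        self._cum += np.cumsum(delta_p)
        self.update_work += int(e - s) + self.partition.num_blocks

    def refresh(self) -> None:
        """Recompute the cumulative block sums from the propensity vector."""
        self.block_sums = init_block_sums(self.propensities, self.partition)
        self._cum = self.block_sums.cumulative
        self._since_refresh = 0
        self.refresh_count += 1
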