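"""Reaction-reaction dependency graph, block-sorted with offset indices.

When reaction ``r`` fires it changes at most four species; only reactions
consuming one of those species see their propensity change.  The graph
stores, for every source reaction, that dependent set sorted by the
propensity block each dependent lives in, together with a per-block
end-offset array so the dependents owned by one block are an O(1) slice.

Each dependent entry is denormalized — it duplicates the reaction type,
rate constant and reactant indices of the dependent reaction — trading
memory for access locality; :func:`check_consistency` compares the copies
against the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_model import ReactionNetwork

__all__ = [
    "DependentEntry",
    "DependencyGraph",
    "build_dependency_graph",
    "dependents_in_block",
    "connectivity_stats",
    "check_consistency",
    "dump_tsv",
]


@dataclass(frozen=True)
class DependentEntry:
    """Denormalized record of one dependent reaction."""

    rtype: int
    reaction_index: int
    rate_constant: float
    reactant_indices: tuple[int, ...]


class DependencyGraph:
    """Per-source dependent lists in CSR form, sorted by owning block.

    Attributes
    ----------
    dep_indices : ndarray of int32
        Flat concatenation of all dependent reaction indices, each source's
        slice sorted non-decreasing by block (block = index // block_size).
    dep_ptr : ndarray of int64, shape (M+1,)
        CSR row pointer: source ``r`` owns ``dep_indices[dep_ptr[r]:dep_ptr[r+1]]``.
    block_offsets : ndarray of int64, shape (M, p)
        ``block_offsets[r, b]`` is the end offset (relative to the start of
        source ``r``'s slice) of the dependents owned by block ``b``; the
        last column equals the slice length.
    """

    def __init__(
        self,
        network: ReactionNetwork,
        block_size: int,
        dep_indices: np.ndarray,
        dep_ptr: np.ndarray,
        block_offsets: np.ndarray,
    ):
        self.network = network
        self.block_size = int(block_size)
        self.num_blocks = block_offsets.shape[1]
        self.dep_indices = dep_indices
        self.dep_ptr = dep_ptr
        self.block_offsets = block_offsets
        # denormalized metadata aligned with dep_indices
        arrays = network.arrays
        self.dep_rtype = arrays.rtype[dep_indices]
        self.dep_rate = arrays.rate[dep_indices]
        self.dep_r1 = arrays.r1[dep_indices]
        self.dep_r2 = arrays.r2[dep_indices]

    def dependents(self, source: int) -> np.ndarray:
        """Dependent reaction indices of one source reaction."""
        return self.dep_indices[self.dep_ptr[source] : self.dep_ptr[source + 1]]

    def entries(self, source: int) -> list[DependentEntry]:
        """Dependents of ``source`` as denormalized records."""
        net = self.network
        return [
            DependentEntry(
                int(net.arrays.rtype[d]),
                int(d),
                float(net.arrays.rate[d]),
                net.reactions[d].reactant_indices,
            )
            for d in self.dependents(source)
        ]


def build_dependency_graph(network: ReactionNetwork, block_size: int) -> DependencyGraph:
    """Build the block-sorted dependency graph of ``network``.

    ``dependents(r) = { m : reactants(m) ∩ changed_species(r) ≠ ∅ }`` —
    a reaction is its own dependent whenever it consumes a species it
    changes, since its propensity must be refreshed after it fires.
    """
    M = network.num_reactions
    num_blocks = -(-M // block_size)
    # consumers[s]: sorted reaction indices that have species s as a reactant
    consumers: dict[int, list[int]] = {}
    for r in network.reactions:
        for s in set(r.reactant_indices):
            consumers.setdefault(s, []).append(r.index)

    ptr = np.zeros(M + 1, dtype=np.int64)
    rows: list[np.ndarray] = []
    offsets = np.zeros((M, num_blocks), dtype=np.int64)
    for r in network.reactions:
        deps: set[int] = set()
        for s in r.changed_species:
            deps.update(consumers.get(s, ()))
        row = np.fromiter(sorted(deps), dtype=np.int32, count=len(deps))
        # reaction indices sort identically to (block, index) lexicographic
        # order because block = index // block_size is monotone in the index
        rows.append(row)
        ptr[r.index + 1] = ptr[r.index] + len(row)
        blocks = row // block_size
        offsets[r.index] = np.searchsorted(blocks, np.arange(num_blocks), side="right")
    dep_indices = (
        np.concatenate(rows) if rows else np.empty(0, dtype=np.int32)
    )
    return DependencyGraph(network, block_size, dep_indices, ptr, offsets)


def dependents_in_block(graph: DependencyGraph, source: int, block_index: int) -> np.ndarray:
    """The dependents of ``source`` owned by one block — O(1) slice arithmetic."""
    if not 0 <= block_index < graph.num_blocks:
        raise IndexError(f"block index {block_index} out of range [0, {graph.num_blocks})")
    base = graph.dep_ptr[source]
    lo = 0 if block_index == 0 else int(graph.block_offsets[source, block_index - 1])
    hi = int(graph.block_offsets[source, block_index])
    return graph.dep_indices[base + lo : base + hi]


def connectivity_stats(graph: DependencyGraph) -> tuple[np.ndarray, float, int]:
    """Per-source dependent counts and their mean and max."""
    counts = np.diff(graph.dep_ptr)
    return counts, float(counts.mean()), int(counts.max())


def check_consistency(graph: DependencyGraph) -> list[str]:
    """Compare the denormalized dependent metadata against the network."""
    arrays = graph.network.arrays
    problems = []
    if not np.array_equal(graph.dep_rtype, arrays.rtype[graph.dep_indices]):
        problems.append("dependent rtype mismatch")
    if not np.array_equal(graph.dep_rate, arrays.rate[graph.dep_indices]):
        problems.append("dependent rate constant mismatch")
    if not np.array_equal(graph.dep_r1, arrays.r1[graph.dep_indices]):
        problems.append("dependent reactant mismatch")
    return problems


def dump_tsv(graph: DependencyGraph, path) -> None:
    """Debug dump: one row per (source, block, dependent) with metadata."""
    with open(path, "w") as fh:
        fh.write("source\tblock\tdependent\trtype\tk\n")
        for r in range(graph.network.num_reactions):
            for b in range(graph.num_blocks):
                for d in dependents_in_block(graph, r, b):
                    fh.write(
                        f"{r}\t{b}\t{int(d)}\t{int(graph.network.arrays.rtype[d])}"
                        f"\t{graph.network.arrays.rate[d]!r}\n"
                    )
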