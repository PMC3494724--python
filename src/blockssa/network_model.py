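"""Reaction-network model: species, mass-action reactions, packed stoichiometry.

A :class:`ReactionNetwork` is the static description of a well-stirred
chemical system: ``N`` species with integer molecular counts and ``M``
mass-action reaction channels of three kinds,

* Type 1 — unimolecular,   ``s_i ->``          with  a = k * [s_i]
* Type 2 — bimolecular,    ``s_i + s_j ->``    with  a = k * [s_i] * [s_j]
* Type 3 — dimerization,   ``2 s_i ->``        with  a = k * [s_i]([s_i]-1)/2

Every reaction changes at most four species, each by a net delta in
{-2, -1, +1, +2}.  The stoichiometry is additionally stored bit-packed
(29-bit species index + 3-bit two's-complement delta per entry); the packed
table is a storage format — simulation kernels work on an unpacked view.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "InvalidModelError",
    "InternalConsistencyError",
    "Species",
    "Reaction",
    "StoichiometricTable",
    "ReactionNetwork",
    "propensity",
    "compute_propensities",
    "pack_stoichiometry",
    "apply_stoichiometry",
    "validate_network",
]

VALID_DELTAS = (-2, -1, 1, 2)
MAX_STOICH_ENTRIES = 4
SPECIES_INDEX_BITS = 29
MAX_SPECIES_INDEX = (1 << SPECIES_INDEX_BITS) - 1
#: packed entry with delta bits 000 — an illegal change, hence a null marker
NULL_ENTRY = np.uint32(0)


class InvalidModelError(ValueError):
    """The network description violates a model invariant."""


class InternalConsistencyError(RuntimeError):
    """Simulation state became inconsistent (signals a propensity bug)."""


@dataclass(frozen=True)
class Species:
    """A chemical species with its initial molecular count."""

    index: int
    name: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise InvalidModelError(
                f"species {self.name!r}: negative initial count {self.count}"
            )


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction channel.

    Parameters
    ----------
    index : int
        Dense 0-based reaction index.
    rtype : int
        1 (unimolecular), 2 (bimolecular, distinct reactants) or
        3 (bimolecular, identical reactants).
    reactant_indices : tuple of int
        One species index for Type 1, two for Types 2/3 (equal for Type 3).
    rate_constant : float
        Stochastic rate constant ``k`` (non-negative).
    stoich : tuple of (int, int)
        Net ``(species_index, delta)`` pairs, delta in {-2,-1,+1,+2},
        at most four entries, species indices unique.
    """

    index: int
    rtype: int
    reactant_indices: tuple[int, ...]
    rate_constant: float
    stoich: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.rtype not in (1, 2, 3):
            raise InvalidModelError(f"reaction {self.index}: unknown rtype {self.rtype}")
        n = len(self.reactant_indices)
        if self.rtype == 1 and n != 1:
            raise InvalidModelError(f"reaction {self.index}: Type 1 needs 1 reactant")
        if self.rtype in (2, 3) and n != 2:
            raise InvalidModelError(f"reaction {self.index}: Type {self.rtype} needs 2 reactants")
        if self.rtype == 2 and self.reactant_indices[0] == self.reactant_indices[1]:
            raise InvalidModelError(
                f"reaction {self.index}: Type 2 reactants must be distinct"
            )
        if self.rtype == 3 and self.reactant_indices[0] != self.reactant_indices[1]:
            raise InvalidModelError(
                f"reaction {self.index}: Type 3 reactants must be identical"
            )
        if self.rate_constant < 0:
            raise InvalidModelError(f"reaction {self.index}: negative rate constant")
        if len(self.stoich) > MAX_STOICH_ENTRIES:
            raise InvalidModelError(
                f"reaction {self.index}: more than {MAX_STOICH_ENTRIES} stoichiometric entries"
            )
        seen: set[int] = set()
        for s, d in self.stoich:
            if d not in VALID_DELTAS:
                raise InvalidModelError(
                    f"reaction {self.index}: delta {d} for species {s} outside {VALID_DELTAS}"
                )
            if s in seen:
                raise InvalidModelError(
                    f"reaction {self.index}: species {s} listed twice in stoichiometry"
                )
            seen.add(s)

    @property
    def changed_species(self) -> tuple[int, ...]:
        return tuple(s for s, _ in self.stoich)


def reaction_from_lists(
    index: int,
    rtype: int,
    reactants: Sequence[int],
    products: Sequence[int],
    rate_constant: float,
) -> Reaction:
    """Build a :class:`Reaction` from reactant/product species lists.

    Net deltas are accumulated (reactants count -1 each, products +1 each);
    a species whose net delta is zero (a pure catalyst) is rejected, since
    the packed format has no encoding for a zero change.
    """
    net: dict[int, int] = {}
    for s in reactants:
        net[s] = net.get(s, 0) - 1
    for s in products:
        net[s] = net.get(s, 0) + 1
    for s, d in net.items():
        if d == 0:
            raise InvalidModelError(
                f"reaction {index}: species {s} has net zero change (catalysts unsupported)"
            )
    stoich = tuple(sorted(net.items()))
    return Reaction(index, rtype, tuple(reactants), float(rate_constant), stoich)


@dataclass
class StoichiometricTable:
    """Flat bit-packed stoichiometry: four ``uint32`` entries per reaction.

    Each entry encodes ``(species_index << 3) | (delta & 0b111)`` with a
    3-bit two's-complement delta; entries with delta bits 000 are null
    padding.  Supports species indices up to 2**29 - 1.
    """

    data: np.ndarray  # shape (M, 4), dtype uint32

    @staticmethod
    def pack_entry(species_index: int, delta: int) -> np.uint32:
        if not 0 <= species_index <= MAX_SPECIES_INDEX:
            raise InvalidModelError(
                f"species index {species_index} exceeds {SPECIES_INDEX_BITS}-bit field"
            )
        if delta not in VALID_DELTAS:
            raise InvalidModelError(f"delta {delta} not in {VALID_DELTAS}")
        return np.uint32((species_index << 3) | (delta & 0b111))

    @staticmethod
    def unpack_entry(entry: int) -> tuple[int, int]:
        e = int(entry)
        bits = e & 0b111
        delta = bits - 8 if bits >= 4 else bits
        return e >> 3, delta

    def entries(self, reaction_index: int) -> list[tuple[int, int]]:
        """Decode the non-null ``(species, delta)`` pairs of one reaction."""
        out = []
        for e in self.data[reaction_index]:
            if int(e) & 0b111:
                out.append(self.unpack_entry(e))
        return out

    @property
    def flat(self) -> np.ndarray:
        """The table as the linear array it is stored as."""
        return self.data.reshape(-1)


def pack_stoichiometry(reactions: Sequence[Reaction]) -> StoichiometricTable:
    """Bit-pack the stoichiometry of all reactions into one table."""
    data = np.full((len(reactions), MAX_STOICH_ENTRIES), NULL_ENTRY, dtype=np.uint32)
    for r in reactions:
        for j, (s, d) in enumerate(r.stoich):
            data[r.index, j] = StoichiometricTable.pack_entry(s, d)
    return StoichiometricTable(data)


class ReactionNetwork:
    """Species table + typed reaction list + packed stoichiometric table."""

    def __init__(self, species: Sequence[Species], reactions: Sequence[Reaction]):
        if len(species) < 1 or len(reactions) < 1:
            raise InvalidModelError("a network needs at least one species and one reaction")
        self.species = list(species)
        self.reactions = list(reactions)
        self.stoich_table = pack_stoichiometry(self.reactions)
        self._arrays: _ReactionArrays | None = None

    # -- basic shape ------------------------------------------------------
    @property
    def num_species(self) -> int:
        return len(self.species)

    @property
    def num_reactions(self) -> int:
        return len(self.reactions)

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def initial_counts(self) -> np.ndarray:
        return np.array([s.count for s in self.species], dtype=np.int64)

    @property
    def arrays(self) -> "_ReactionArrays":
        """Cached vectorized view of the reaction list (simulation fast path)."""
        if self._arrays is None:
            self._arrays = _ReactionArrays(self)
        return self._arrays

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReactionNetwork):
            return NotImplemented
        return self.species == other.species and self.reactions == other.reactions


class _ReactionArrays:
    """Column-oriented reaction data used by the simulation engines.

    Propensities of all three reaction types are computed with one fused
    expression ``a = keff * c1 * (c2 - off)`` where ``c2`` reads a dummy
    species pinned at count 1 for Type 1 reactions, ``keff = k/2`` and
    ``off = 1`` for Type 3.
    """

    def __init__(self, network: ReactionNetwork):
        M = network.num_reactions
        N = network.num_species
        self.num_species = N
        self.num_reactions = M
        self.rtype = np.array([r.rtype for r in network.reactions], dtype=np.int8)
        self.rate = np.array([r.rate_constant for r in network.reactions])
        self.r1 = np.array([r.reactant_indices[0] for r in network.reactions], dtype=np.int64)
        r2 = np.empty(M, dtype=np.int64)
        keff = self.rate.copy()
        off = np.zeros(M)
        for m, r in enumerate(network.reactions):
            if r.rtype == 1:
                r2[m] = N  # dummy species, count 1
            elif r.rtype == 2:
                r2[m] = r.reactant_indices[1]
            else:
                r2[m] = r.reactant_indices[0]
                keff[m] *= 0.5
                off[m] = 1.0
        self.r2 = r2
        self.keff = keff
        self.off = off
        # trimmed per-reaction stoichiometry (unpacked view of the table)
        self.sto_idx = [
            np.array([s for s, _ in r.stoich], dtype=np.int64) for r in network.reactions
        ]
        self.sto_delta = [
            np.array([d for _, d in r.stoich], dtype=np.float64) for r in network.reactions
        ]

    def state_vector(self, counts: np.ndarray) -> np.ndarray:
        """Counts as float64 with the trailing dummy species pinned at 1."""
        state = np.empty(self.num_species + 1)
        state[:-1] = counts
        state[-1] = 1.0
        return state

    def propensities(self, state: np.ndarray, idx: np.ndarray | None = None) -> np.ndarray:
        """Mass-action propensities for all reactions, or the subset ``idx``.

        ``state`` must come from :meth:`state_vector`.
        """
        if idx is None:
            c1 = state[self.r1]
            a = self.keff * c1 * (state[self.r2] - self.off)
        else:
            c1 = state[self.r1[idx]]
            a = self.keff[idx] * c1 * (state[self.r2[idx]] - self.off[idx])
        return a + 0.0  # normalize -0.0 from empty Type-3 channels


def propensity(reaction: Reaction, counts: Sequence[int] | np.ndarray) -> float:
    """Exact mass-action propensity of one reaction at the given counts."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    k = reaction.rate_constant
    if reaction.rtype == 1:
        return float(k * counts[reaction.reactant_indices[0]])
    if reaction.rtype == 2:
        i, j = reaction.reactant_indices
        return float(k * counts[i] * counts[j])
    if reaction.rtype == 3:
        c = int(counts[reaction.reactant_indices[0]])
        return float(k * c * (c - 1) / 2.0)
    raise InvalidModelError(f"unknown rtype {reaction.rtype}")


def compute_propensities(network: ReactionNetwork, counts: np.ndarray) -> np.ndarray:
    """Propensity vector for all reactions of ``network`` at ``counts``."""
    arrays = network.arrays
    return arrays.propensities(arrays.state_vector(np.asarray(counts)))


def apply_stoichiometry(
    counts: np.ndarray, reaction_index: int, stoich_table: StoichiometricTable
) -> np.ndarray:
    """Apply the firing of one reaction to a count vector.

    Returns a new array; raises :class:`InternalConsistencyError` if any
    count would go negative (the caller selected a reaction with zero
    propensity — a bookkeeping bug, not a user error).
    """
    out = np.array(counts, copy=True)
    for s, d in stoich_table.entries(reaction_index):
        out[s] += d
        if out[s] < 0:
            raise InternalConsistencyError(
                f"firing reaction {reaction_index} drives species {s} negative"
            )
    return out


def validate_network(network: ReactionNetwork) -> list[str]:
    """Check every type invariant; returns human-readable violations.

    Reports instead of raising so a CLI ``validate`` run can list all
    problems at once.  An empty list means the network is well formed.
    """
    violations: list[str] = []
    N = network.num_species
    for i, sp in enumerate(network.species):
        if sp.index != i:
            violations.append(f"species {sp.name!r}: index {sp.index} not dense (expected {i})")
        if sp.count < 0:
            violations.append(f"species {sp.name!r}: negative count {sp.count}")
    for m, r in enumerate(network.reactions):
        tag = f"reaction {m}"
        if r.index != m:
            violations.append(f"{tag}: index {r.index} not dense")
        for s in r.reactant_indices:
            if not 0 <= s < N:
                violations.append(f"{tag}: reactant species index {s} out of range")
        for s, d in r.stoich:
            if not 0 <= s < N:
                violations.append(f"{tag}: stoichiometry references species index {s} out of range")
            if d not in VALID_DELTAS:
                violations.append(f"{tag}: delta {d} outside {VALID_DELTAS}")
        if len(r.stoich) > MAX_STOICH_ENTRIES:
            violations.append(f"{tag}: more than {MAX_STOICH_ENTRIES} stoichiometric entries")
        if r.rtype not in (1, 2, 3):
            violations.append(f"{tag}: unknown rtype {r.rtype}")
            continue
        if r.rtype == 1 and len(r.reactant_indices) != 1:
            violations.append(f"{tag}: Type 1 must have exactly one reactant")
        if r.rtype in (2, 3) and len(r.reactant_indices) != 2:
            violations.append(f"{tag}: Type {r.rtype} must have two reactants")
        if r.rtype == 2 and r.reactant_indices[0] == r.reactant_indices[1]:
            violations.append(f"{tag}: Type 2 reactants must be distinct")
        if r.rtype == 3 and r.reactant_indices[0] != r.reactant_indices[1]:
            violations.append(f"{tag}: Type 3 reactants must be identical")
        if r.rate_constant < 0:
            violations.append(f"{tag}: negative rate constant")
        # reactant-side consistency: each reactant must be consumed unless it
        # also appears as a product (net delta may then stay in range)
        net = dict(r.stoich)
        consumed = {}
        for s in r.reactant_indices:
            consumed[s] = consumed.get(s, 0) + 1
        for s, c in consumed.items():
            d = net.get(s)
            if d is None:
                violations.append(
                    f"{tag}: reactant {s} has net zero change (catalysts unsupported)"
                )
            elif d > -c + 2:  # can regain at most +2 from products
                violations.append(f"{tag}: reactant {s} delta {d} inconsistent with rtype")
    return violations
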