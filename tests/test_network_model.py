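"""Propensity formulas, packed stoichiometry, state updates, validation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from blockssa import (
    InternalConsistencyError,
    InvalidModelError,
    ReactionNetwork,
    Species,
    StoichiometricTable,
    apply_stoichiometry,
    compute_propensities,
    pack_stoichiometry,
    propensity,
    validate_network,
)
from blockssa.network_model import (
    MAX_SPECIES_INDEX,
    Reaction,
    reaction_from_lists,
)


def _reaction(rtype, reactants, products, k, index=0):
    return reaction_from_lists(index, rtype, reactants, products, k)


def _forge(index, rtype, reactant_indices, k, stoich):
    """Bypass constructor validation to build a deliberately broken reaction."""
    r = object.__new__(Reaction)
    object.__setattr__(r, "index", index)
    object.__setattr__(r, "rtype", rtype)
    object.__setattr__(r, "reactant_indices", reactant_indices)
    object.__setattr__(r, "rate_constant", k)
    object.__setattr__(r, "stoich", stoich)
    return r


class TestPropensity:
    @pytest.mark.parametrize(
        "rtype,reactants,k,counts,expected",
        [
            (1, [0], 2.0, [5, 0], 10.0),          # a = k [s]
            (3, [0, 0], 1.0, [1, 0], 0.0),         # [s]([s]-1)/2 with one molecule
            (2, [0, 1], 0.5, [4, 6], 12.0),        # a = k [s_i][s_j]
            (3, [0, 0], 2.0, [5, 0], 20.0),        # k C(5,2)
            (1, [0], 3.0, [0, 1], 0.0),
        ],
    )
    def test_mass_action_forms(self, rtype, reactants, k, counts, expected):
        r = _reaction(rtype, reactants, [max(reactants) + 1], k)
        assert propensity(r, counts) == expected

    def test_unknown_rtype_rejected(self):
        r = _forge(0, 7, (0,), 1.0, ((0, -1), (1, 1)))
        with pytest.raises(InvalidModelError):
            propensity(r, [3, 0])

    @pytest.mark.parametrize("rtype", [1, 2, 3])
    def test_zero_iff_cannot_fire(self, rtype):
        """a = 0 exactly when firing would drive a reactant count negative."""
        if rtype == 1:
            r = _reaction(1, [0], [1], 1.0)
            feasible = lambda c: c[0] >= 1
        elif rtype == 2:
            r = _reaction(2, [0, 1], [2], 1.0)
            feasible = lambda c: c[0] >= 1 and c[1] >= 1
        else:
            r = _reaction(3, [0, 0], [1], 1.0)
            feasible = lambda c: c[0] >= 2
        for c0 in range(11):
            for c1 in range(11):
                counts = [c0, c1, 0]
                assert (propensity(r, counts) > 0) == feasible(counts)

    def test_vectorized_matches_scalar(self, toy_network):
        counts = toy_network.initial_counts()
        vec = compute_propensities(toy_network, counts)
        scal = [propensity(r, counts) for r in toy_network.reactions]
        np.testing.assert_array_equal(vec, scal)
        assert abs(vec.sum() - sum(scal)) <= 1e-9 * max(vec.sum(), 1.0)


class TestPackedStoichiometry:
    def test_a_plus_b_to_c_layout(self):
        r = _reaction(2, [0, 1], [2], 1.0)
        table = pack_stoichiometry([r])
        assert table.data.shape == (1, 4)
        assert table.entries(0) == [(0, -1), (1, -1), (2, 1)]
        assert int(table.data[0, 3]) & 0b111 == 0  # null padding slot

    def test_dimerization_two_entries(self):
        r = _reaction(3, [0, 0], [1], 1.0)
        table = pack_stoichiometry([r])
        assert table.entries(0) == [(0, -2), (1, 1)]
        assert [int(e) & 0b111 != 0 for e in table.data[0]] == [True, True, False, False]

    def test_species_index_field_bound(self):
        assert StoichiometricTable.unpack_entry(
            StoichiometricTable.pack_entry(MAX_SPECIES_INDEX, -2)
        ) == (MAX_SPECIES_INDEX, -2)
        with pytest.raises(InvalidModelError):
            StoichiometricTable.pack_entry(MAX_SPECIES_INDEX + 1, 1)

    @pytest.mark.parametrize("delta", [-3, 0, 3])
    def test_invalid_delta_rejected(self, delta):
        with pytest.raises(InvalidModelError):
            StoichiometricTable.pack_entry(0, delta)

    @given(
        st.lists(
            st.tuples(
                st.integers(0, MAX_SPECIES_INDEX),
                st.sampled_from([-2, -1, 1, 2]),
            ),
            min_size=1,
            max_size=4,
        )
    )
    def test_pack_unpack_roundtrip(self, entries):
        packed = [StoichiometricTable.pack_entry(s, d) for s, d in entries]
        assert [StoichiometricTable.unpack_entry(e) for e in packed] == entries

    def test_flat_view_is_linear(self, toy_network):
        table = toy_network.stoich_table
        assert table.flat.shape == (toy_network.num_reactions * 4,)


class TestApplyStoichiometry:
    def test_bimolecular_firing(self):
        net = ReactionNetwork(
            [Species(0, "A", 3), Species(1, "B", 2), Species(2, "C", 0)],
            [_reaction(2, [0, 1], [2], 1.0)],
        )
        out = apply_stoichiometry([3, 2, 0], 0, net.stoich_table)
        assert out.tolist() == [2, 1, 1]

    def test_dimerization_firing(self):
        net = ReactionNetwork(
            [Species(0, "A", 5), Species(1, "B", 0)],
            [_reaction(3, [0, 0], [1], 1.0)],
        )
        out = apply_stoichiometry([5, 0], 0, net.stoich_table)
        assert out.tolist() == [3, 1]

    def test_infeasible_firing_is_a_bug(self):
        net = ReactionNetwork(
            [Species(0, "A", 1), Species(1, "B", 0)],
            [_reaction(3, [0, 0], [1], 1.0)],
        )
        with pytest.raises(InternalConsistencyError):
            apply_stoichiometry([1, 0], 0, net.stoich_table)


class TestValidation:
    def test_well_formed_chain(self, chain5):
        assert validate_network(chain5) == []

    def test_out_of_range_species_reference(self, chain5):
        bad = _forge(0, 1, (5,), 1.0, ((5, -1), (0, 1)))
        net = ReactionNetwork.__new__(ReactionNetwork)
        net.species = chain5.species
        net.reactions = [bad]
        net._arrays = None
        problems = validate_network(net)
        assert any("out of range" in p for p in problems)

    def test_type2_equal_reactants_flagged(self, chain5):
        bad = _forge(0, 2, (1, 1), 1.0, ((1, -2), (2, 1)))
        net = ReactionNetwork.__new__(ReactionNetwork)
        net.species = chain5.species
        net.reactions = [bad]
        net._arrays = None
        problems = validate_network(net)
        assert any("distinct" in p for p in problems)

    def test_catalyst_rejected_at_construction(self):
        with pytest.raises(InvalidModelError, match="net zero"):
            reaction_from_lists(0, 2, [0, 1], [0, 2], 1.0)

    def test_too_many_changed_species(self):
        with pytest.raises(InvalidModelError):
            reaction_from_lists(0, 2, [0, 1], [2, 3, 4], 1.0)
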