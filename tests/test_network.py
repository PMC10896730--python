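import numpy as np
import pytest
from hypothesis import given, strategies as st

from metaboloq.network import (
    GeneralizedReaction,
    ParameterDef,
    SpeciesDef,
    StateDomainError,
    UnknownIdError,
    ValidationError,
    conservation_laws,
    derivative,
    make_network,
    rate_vector,
    reaction_rate,
    stoichiometry_matrix,
    symbolic_odes,
)


def toy_ab():
    """A -> B with rate k*A."""
    return make_network(
        [SpeciesDef("A", "A", 1.0), SpeciesDef("B", "B", 0.0)],
        [ParameterDef("k", 2.0)],
        [GeneralizedReaction("r", "k", (("A", 1),), {"A": -1, "B": 1})],
    )


class TestMakeNetwork:
    def test_minimal_decay_network(self):
        net = make_network(
            [SpeciesDef("A", "species A", 1.0)],
            [ParameterDef("k", 1.0)],
            [GeneralizedReaction("r", "k", (("A", 1),), {"A": -1})],
        )
        assert net.n_species == 1 and net.n_reactions == 1

    def test_dangling_species_reference(self):
        with pytest.raises(UnknownIdError, match="x99"):
            make_network(
                [SpeciesDef("A", "A", 1.0)],
                [ParameterDef("k", 1.0)],
                [GeneralizedReaction("r", "k", (("x99", 1),), {"A": -1})],
            )

    def test_dangling_parameter_reference(self):
        with pytest.raises(UnknownIdError, match="kX"):
            make_network(
                [SpeciesDef("A", "A", 1.0)],
                [ParameterDef("k", 1.0)],
                [GeneralizedReaction("r", "kX", (("A", 1),), {"A": -1})],
            )

    @pytest.mark.parametrize("dup", ["species", "parameter", "reaction"])
    def test_duplicate_ids_rejected(self, dup):
        species = [SpeciesDef("A", "A", 1.0)]
        params = [ParameterDef("k", 1.0)]
        reactions = [GeneralizedReaction("r", "k", (("A", 1),), {"A": -1})]
        if dup == "species":
            species.append(SpeciesDef("A", "again", 0.0))
        elif dup == "parameter":
            params.append(ParameterDef("k", 2.0))
        else:
            reactions.append(GeneralizedReaction("r", "k", (("A", 1),), {"A": -1}))
        with pytest.raises(ValidationError, match="duplicate"):
            make_network(species, params, reactions)

    def test_negative_initial_rejected(self):
        with pytest.raises(ValidationError):
            SpeciesDef("A", "A", -0.1)

    def test_empty_rate_factors_rejected(self):
        with pytest.raises(ValidationError):
            GeneralizedReaction("r", "k", (), {"A": -1})


class TestReactionRate:
    def test_r1_at_printed_initial_state(self, canonical):
        # k1 * x1 * x2 * x3 = 5 * 0.6 * 1.1 * 4.6
        flux = reaction_rate(canonical, "r1", canonical.initial_state())
        assert flux == pytest.approx(15.18, abs=1e-12)

    def test_all_reactions_zero_at_zero_state(self, canonical):
        zero = np.zeros(canonical.n_species)
        assert np.all(rate_vector(canonical, zero) == 0.0)

    def test_r5_zero_at_initial_state(self, canonical):
        # x12(0) = 0 annihilates the ETFDH reduction flux
        assert reaction_rate(canonical, "r5", canonical.initial_state()) == 0.0

    def test_small_negative_state_clamped(self, canonical):
        state = canonical.initial_state()
        state[4] = -5e-10  # within round-off tolerance
        assert reaction_rate(canonical, "r1", state) == pytest.approx(15.18)

    def test_negative_state_beyond_tolerance_rejected(self, canonical):
        state = canonical.initial_state()
        state[0] = -1e-6
        with pytest.raises(StateDomainError, match="x1"):
            reaction_rate(canonical, "r1", state)

    @given(scale=st.floats(0.0, 100.0, allow_nan=False))
    def test_rate_homogeneous_in_rate_constant(self, scale):
        net = toy_ab()
        base = reaction_rate(net, "r", [3.0, 0.0])
        scaled = reaction_rate(net, "r", [3.0, 0.0], parameters={"k": 2.0 * scale})
        assert scaled == base * scale


class TestDerivative:
    def test_dx2_at_printed_initial_state(self, canonical):
        # both monomer oxidations consume cytochrome c: -2 * 15.18
        d = derivative(canonical, canonical.initial_state())
        assert d[1] == pytest.approx(-30.36, abs=1e-12)

    def test_dx9_zero_at_initial_state(self, canonical):
        d = derivative(canonical, canonical.initial_state())
        assert d[8] == 0.0

    def test_zero_rate_constants_give_zero_field(self, canonical):
        zeroed = canonical.with_updates(
            parameter_values={p.id: 0.0 for p in canonical.parameters})
        assert np.all(derivative(zeroed, canonical.initial_state()) == 0.0)

    @given(
        state=st.lists(st.floats(0.0, 10.0, allow_nan=False), min_size=14, max_size=14)
    )
    def test_derivative_equals_stoichiometry_times_rates(self, canonical, state):
        state = np.array(state)
        S = stoichiometry_matrix(canonical)
        assert np.array_equal(
            derivative(canonical, state), S @ rate_vector(canonical, state)
        )


class TestStoichiometryMatrix:
    def test_toy_network_column(self):
        S = stoichiometry_matrix(toy_ab())
        assert S.tolist() == [[-1], [1]]

    def test_r7_column(self, canonical):
        S = stoichiometry_matrix(canonical)
        col = S[:, canonical.reaction_ids.index("r7")]
        expected = np.zeros(14, dtype=int)
        for sid, v in {"x1": 1, "x7": 1, "x3": -1, "x12": -1, "x13": -1}.items():
            expected[canonical.species_index(sid)] = v
        assert np.array_equal(col, expected)

    def test_r2_kinetic_only_species_has_zero_net_change(self, canonical):
        # x7 appears in r2's rate law but r2 neither makes nor consumes it
        S = stoichiometry_matrix(canonical)
        assert S[canonical.species_index("x7"), canonical.reaction_ids.index("r2")] == 0
        assert ("x7", 1) in canonical.reactions[1].rate_factors


class TestConservationLaws:
    def test_toy_total_mass(self):
        laws = conservation_laws(toy_ab())
        assert len(laws) == 1
        assert laws[0].tolist() == [1, 1]

    def test_open_system_has_no_laws(self):
        net = make_network(
            [SpeciesDef("A", "A", 0.5)],
            [ParameterDef("k", 1.0)],
            [GeneralizedReaction("r", "k", (("A", 1),), {"A": 1})],
        )
        assert conservation_laws(net) == []

    def test_basis_annihilates_stoichiometry_exactly(self, canonical):
        S = stoichiometry_matrix(canonical)
        laws = conservation_laws(canonical)
        assert len(laws) == canonical.n_species - np.linalg.matrix_rank(S)
        for v in laws:
            assert np.all(v @ S == 0)
            first = v[np.nonzero(v)[0][0]]
            assert first > 0

    @pytest.mark.parametrize(
        "pool",
        [
            {"x2": 1, "x5": 1},
            {"x9": 1, "x10": 1, "x11": 1},
            {"x1": 1, "x4": 1, "x7": 1, "x12": 1, "x13": 1, "x14": 1},
        ],
        ids=["cytc", "etfdh", "quinone"],
    )
    def test_documented_pools_lie_in_the_basis_span(self, canonical, pool):
        vec = np.zeros(14)
        for sid, c in pool.items():
            vec[canonical.species_index(sid)] = c
        basis = np.array(conservation_laws(canonical), dtype=float).T
        coef, residual, *_ = np.linalg.lstsq(basis, vec, rcond=None)
        assert np.allclose(basis @ coef, vec, atol=1e-10)


class TestSymbolicODEs:
    def test_x5_terms_keep_monomer_reactions_distinct(self, canonical):
        odes = {o.species_id: o for o in symbolic_odes(canonical)}
        assert odes["x5"].terms == ((1, "r1"), (1, "r3"))

    def test_x3_consumed_by_every_reaction(self, canonical):
        odes = {o.species_id: o for o in symbolic_odes(canonical)}
        assert odes["x3"].terms == tuple(
            (-1, f"r{j}") for j in range(1, 8)
        )

    def test_untouched_species_has_empty_equation(self):
        net = make_network(
            [SpeciesDef("A", "A", 1.0), SpeciesDef("Z", "Z", 1.0)],
            [ParameterDef("k", 1.0)],
            [GeneralizedReaction("r", "k", (("A", 1),), {"A": -1})],
        )
        odes = {o.species_id: o for o in symbolic_odes(net)}
        assert odes["Z"].terms == ()
        assert odes["Z"].render() == "dZ/dt = 0"
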