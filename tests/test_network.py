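"""Structural and rate-law checks of the stoichiometric network."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hpaxis.network import (
    N_SPECIES,
    RATE_CONSTANTS,
    SPECIES,
    SpeciesState,
    build_rat_network,
    initial_state,
    mass_action_jacobian,
    mass_action_rhs,
    network_to_frame,
    reaction_rate,
)


@pytest.fixture(scope="module")
def network():
    return build_rat_network()


class TestStructure:
    def test_species_and_reaction_counts(self, network):
        assert len(network.species) == 11
        assert len(set(network.species)) == 11
        assert len(network.reactions) == 25
        assert [r.label for r in network.reactions] == [f"R{i}" for i in range(1, 26)]

    def test_feedback_stoichiometries(self, network):
        r14 = network.reaction("R14")
        assert dict(r14.reactants) == {"DCTS": 1, "CTS": 2}
        assert dict(r14.products) == {"CTS": 3}
        r15 = network.reaction("R15")
        assert dict(r15.reactants) == {"ALDO": 1, "CTS": 2}
        assert dict(r15.products) == {"CTS": 1}
        assert r15.net_stoichiometry() == {"ALDO": -1, "CTS": -1}

    def test_degradation_steps_have_no_products(self, network):
        r16 = network.reaction("R16")
        assert dict(r16.reactants) == {"CRH": 1, "CTS": 1}
        for label in ["R16", "R17"] + [f"R{i}" for i in range(18, 26)]:
            assert not network.reaction(label).products

    def test_stoichiometry_matrix_column_r14(self, network):
        col = network.stoichiometry_matrix[:, 13]
        expected = np.zeros(N_SPECIES, dtype=int)
        expected[SPECIES.index("CTS")] = 1
        expected[SPECIES.index("DCTS")] = -1
        np.testing.assert_array_equal(col, expected)

    def test_circadian_flag_only_on_crh_production(self, network):
        assert [r.label for r in network.reactions if r.forced_by_circadian] == ["R2"]

    def test_rate_constant_defaults_match_table(self, network):
        assert network.rate_constants() == RATE_CONSTANTS
        assert RATE_CONSTANTS["k1"] == 5.5200e-5
        assert RATE_CONSTANTS["k2"] == 2.2875e-8
        assert RATE_CONSTANTS["k14"] == 1.5120e12
        assert RATE_CONSTANTS["k25"] == 1.0000e-5
        assert all(v > 0 for v in RATE_CONSTANTS.values())

    def test_units_follow_reaction_order(self, network):
        assert network.reaction("R1").units == "M min^-1"
        assert network.reaction("R8").units == "min^-1"
        assert network.reaction("R16").units == "M^-1 min^-1"
        assert network.reaction("R14").units == "M^-2 min^-1"

    def test_custom_rate_constants_and_unknown_key(self):
        net = build_rat_network({"k2": 1e-9})
        assert net.reaction("R2").rate_constant == 1e-9
        with pytest.raises(ValueError, match="unknown rate constants"):
            build_rat_network({"k26": 1.0})

    def test_table_export_round_trips_constants(self, network):
        df = network_to_frame(network)
        assert len(df) == 25
        assert df.set_index("label").loc["R14", "rate_constant"] == 1.5120e12
        assert df.set_index("label").loc["R15", "reactants"] == "ALDO + 2CTS"


class TestReactionRate:
    def test_third_order_positive_feedback_flux(self, network):
        state = initial_state().with_concentration("DCTS", 4e-9).with_concentration("CTS", 4e-8)
        flux = reaction_rate(network.reaction("R14"), state)
        assert flux == pytest.approx(1.5120e12 * 4e-9 * (4e-8) ** 2, rel=1e-14)
        assert flux == pytest.approx(9.6768e-12, rel=1e-12)

    def test_zeroth_order_rates_at_zero_state(self, network):
        zero = SpeciesState(np.zeros(N_SPECIES))
        assert reaction_rate(network.reaction("R1"), zero) == RATE_CONSTANTS["k1"]
        assert reaction_rate(network.reaction("R2"), zero, circadian_factor=0.5) == (
            pytest.approx(RATE_CONSTANTS["k2"] * 0.5)
        )

    def test_zero_reactant_gives_zero_flux(self, network):
        state = initial_state().with_concentration("CRH", 0.0)
        assert reaction_rate(network.reaction("R16"), state) == 0.0

    def test_negative_concentration_rejected(self, network):
        bad = np.full(N_SPECIES, 1e-9)
        bad[0] = -1e-12
        with pytest.raises(ValueError):
            reaction_rate(network.reaction("R1"), bad)


class TestMassActionRhs:
    def test_zero_state_only_synthesis_terms_survive(self):
        d = mass_action_rhs(np.zeros(N_SPECIES), circadian_factor=1.0)
        expected = np.zeros(N_SPECIES)
        expected[SPECIES.index("CHOL")] = RATE_CONSTANTS["k1"]
        expected[SPECIES.index("CRH")] = RATE_CONSTANTS["k2"]
        expected[SPECIES.index("ALDO")] = RATE_CONSTANTS["k3"]
        np.testing.assert_allclose(d, expected, rtol=0, atol=0)

    def test_cts_balance_from_dcts_cts_state(self):
        """d[CTS]/dt from the default constants at [DCTS]=4e-9, [CTS]=4e-8.

        Frozen from the independent stoichiometric oracle:
        k8*DCTS + k14*DCTS*CTS^2 - k9*CTS - k21*CTS = -2.9438992e-9.
        """
        state = np.zeros(N_SPECIES)
        state[SPECIES.index("DCTS")] = 4e-9
        state[SPECIES.index("CTS")] = 4e-8
        d = mass_action_rhs(state)
        assert d[SPECIES.index("CTS")] == pytest.approx(-2.9438992e-9, rel=1e-10)

    def test_cortisol_balance_identity(self, rng):
        for _ in range(20):
            c = 10 ** rng.uniform(-14, -3, N_SPECIES)
            d = mass_action_rhs(c)
            i = SPECIES.index("CORT")
            bal = (d[i] + RATE_CONSTANTS["k23"] * c[i]
                   - RATE_CONSTANTS["k13"] * c[SPECIES.index("HPGS")])
            assert abs(bal) <= 1e-20 + 1e-12 * abs(d[i])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mass_action_rhs(np.zeros(7))


class TestAgainstStoichiometricOracle:
    """The hand-coded RHS must equal S @ v built from the network object."""

    def oracle(self, network, c, factor=1.0):
        v = np.array([reaction_rate(r, c, factor) for r in network.reactions])
        return network.stoichiometry_matrix @ v

    def test_rhs_equals_matrix_product_on_random_states(self, network, rng):
        for _ in range(1000):
            c = 10 ** rng.uniform(-14, -3, N_SPECIES)
            factor = rng.uniform(0.05, 1.0)
            expected = self.oracle(network, c, factor)
            got = mass_action_rhs(c, circadian_factor=factor)
            scale = np.maximum(np.abs(expected), 1e-300)
            assert np.max(np.abs(got - expected) / scale) <= 1e-12

    def test_nonnegativity_forward_invariance(self, network, rng):
        """A species at zero can only be produced: its derivative is >= 0."""
        for _ in range(200):
            c = 10 ** rng.uniform(-14, -3, N_SPECIES)
            i = rng.integers(N_SPECIES)
            c[i] = 0.0
            assert mass_action_rhs(c)[i] >= 0.0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        alpha=st.floats(min_value=0.01, max_value=100.0,
                        allow_nan=False, allow_infinity=False),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_flux_scaling_matches_reaction_order(self, alpha, seed):
        """Scaling all concentrations by alpha scales order-n fluxes by alpha^n."""
        network = build_rat_network()
        c = 10 ** np.random.default_rng(seed).uniform(-12, -6, N_SPECIES)
        for r in network.reactions:
            base = reaction_rate(r, c)
            scaled = reaction_rate(r, alpha * c)
            assert scaled == pytest.approx(alpha ** r.order * base, rel=1e-12)

    def test_analytic_jacobian_matches_finite_differences(self, rng):
        c = 10 ** rng.uniform(-12, -6, N_SPECIES)
        J = mass_action_jacobian(c)
        for j in range(N_SPECIES):
            h = c[j] * 1e-6
            e = np.zeros(N_SPECIES)
            e[j] = h
            fd = (mass_action_rhs(c + e) - mass_action_rhs(c - e)) / (2 * h)
            # tolerance limited by finite-difference cancellation, not the kernel
            np.testing.assert_allclose(J[:, j], fd, rtol=1e-3, atol=1e-8 * np.abs(J).max())
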