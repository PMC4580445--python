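import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nichesim.network import (
    ConfigurationError,
    NetworkDefinitionError,
    Reaction,
    ReactionNetwork,
    Species,
    SystemState,
    build_network,
    build_niche_model,
    conserved_moieties,
    is_conserved,
    load_network,
    network_from_config,
    network_to_config,
    propensity,
    save_network,
)


def ab_network(a=0.01, x_a=10, x_b=100):
    return ReactionNetwork(
        [Species("A", "cell", x_a), Species("B", "cell", x_b),
         Species("AB", "complex", 0)],
        [Reaction("bind", ["A", "B"], ["AB"], a, "binding")],
    )


class TestBuildNetwork:
    def test_pure_death_stoichiometry(self):
        net = build_network(
            [Species("A", "cell", 5)], [Reaction("death", ["A"], [], 1.0, "death")]
        )
        assert net.nu.shape == (1, 1)
        assert net.nu[0, 0] == -1

    def test_dimerization_stoichiometry(self):
        net = ab_network()
        assert list(net.nu[:, 0]) == [-1, -1, 1]

    def test_catalytic_channel_leaves_catalyst_unchanged(self):
        net = build_network(
            [Species("MET", "cell", 1), Species("act_bcat", "intracellular-signal", 1)],
            [Reaction("renew", ["MET", "act_bcat"], ["MET", "MET", "act_bcat"],
                      1.0, "renewal")],
        )
        assert net.nu[net.species_index("act_bcat"), 0] == 0
        assert net.nu[net.species_index("MET"), 0] == 1

    def test_unknown_species_rejected(self):
        with pytest.raises(NetworkDefinitionError):
            build_network(
                [Species("A", "cell", 1)],
                [Reaction("r", ["A", "Z"], [], 1.0, "death")],
            )

    def test_duplicate_species_rejected(self):
        with pytest.raises(NetworkDefinitionError):
            build_network(
                [Species("A", "cell", 1), Species("A", "cell", 2)],
                [Reaction("r", ["A"], [], 1.0, "death")],
            )

    def test_termolecular_rejected(self):
        with pytest.raises(ValueError):
            Reaction("r", ["A", "A", "A"], [], 1.0, "binding")

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            Reaction("r", ["A"], [], -1.0, "death")

    def test_apply_reaction_matches_multisets(self):
        net = ab_network()
        x = np.array([10, 100, 0])
        assert list(net.apply_reaction(x, 0)) == [9, 99, 1]


class TestPropensity:
    def test_linear(self):
        net = build_network(
            [Species("A", "cell", 1000)], [Reaction("death", ["A"], [], 1.0, "death")]
        )
        assert propensity(net, net.initial_state(), 0) == pytest.approx(1000.0)

    def test_absent_reactant_gives_zero(self):
        net = ab_network(x_a=0, x_b=100)
        assert propensity(net, net.initial_state(), 0) == 0.0

    def test_bimolecular_hand_value(self):
        # a * x_A * x_B = 0.01 * 10 * 100 = 10
        net = ab_network()
        assert propensity(net, net.initial_state(), 0) == pytest.approx(10.0)

    def test_homodimer_combinatorics(self):
        net = build_network(
            [Species("A", "cell", 5), Species("AA", "complex", 0)],
            [Reaction("dim", ["A", "A"], ["AA"], 2.0, "binding")],
        )
        # a * x(x-1)/2 = 2 * 10 = 20
        assert propensity(net, net.initial_state(), 0) == pytest.approx(20.0)

    @given(st.floats(0.1, 100.0), st.integers(0, 50), st.integers(0, 50))
    def test_homogeneous_in_rate_constant(self, s, xa, xb):
        base = ab_network(x_a=xa, x_b=xb)
        scaled = base.with_scaled_rates({"bind": s})
        st8 = SystemState(0.0, np.array([xa, xb, 0]))
        assert propensity(scaled, st8, 0) == pytest.approx(s * propensity(base, st8, 0))

    def test_matrix_input_matches_vector(self):
        net = ab_network()
        X = np.array([[10, 100, 0], [3, 7, 1]])
        R = net.propensities(X)
        assert R.shape == (2, 1)
        assert R[0, 0] == pytest.approx(10.0)
        assert R[1, 0] == pytest.approx(0.01 * 21)


class TestConservedMoieties:
    def test_dimerization_moieties(self):
        net = build_network(
            [Species("A", "cell", 1), Species("B", "cell", 1),
             Species("AB", "complex", 0)],
            [Reaction("bind", ["A", "B"], ["AB"], 1.0, "binding"),
             Reaction("unbind", ["AB"], ["A", "B"], 1.0, "dissociation")],
        )
        assert is_conserved(net, {"A": 1, "AB": 1})
        assert is_conserved(net, {"B": 1, "AB": 1})
        ws = conserved_moieties(net)
        assert all((w @ net.nu == 0).all() for w in ws)
        assert len(ws) == 2

    def test_niche_stat3_moiety_conserved(self):
        net = build_niche_model()
        assert is_conserved(net, {"Stat3": 1, "act_Stat3": 1})

    def test_niche_il6_not_conserved(self):
        net = build_niche_model()
        # transcription creates IL-6, so the IL-6 moiety is not conserved
        assert not is_conserved(net, {"IL6": 1, "IL6_gp130": 1, "Let7_IL6": 1})
        for w in conserved_moieties(net):
            assert w[net.species_index("IL6")] == 0

    def test_every_binding_pair_conserves_receptor_moiety(self):
        net = build_niche_model()
        pairs = {
            "gp130": "IL6_gp130", "CXCR1": "IL8_CXCR1",
            "TGFbR2": "TGFb_TGFbR2", "EGFR": "HER2_EGFR",
        }
        for receptor, complex_name in pairs.items():
            w = np.zeros(net.d)
            w[net.species_index(receptor)] = 1
            w[net.species_index(complex_name)] = 1
            for label in (f"bind_{complex_name.replace('_', '_')}",):
                pass
            bind = net.nu[:, [net.reaction_index(r.label)
                              for r in net.reactions
                              if complex_name in r.products or complex_name in r.reactants]]
            # receptor + complex unchanged by its binding/dissociation pair
            for lbl in [r.label for r in net.reactions
                        if set(r.products) == {complex_name}
                        or set(r.reactants) == {complex_name}]:
                j = net.reaction_index(lbl)
                assert w @ net.nu[:, j] == 0


class TestNicheModel:
    def test_channel_and_species_counts(self):
        net = build_niche_model()
        assert net.c == 37
        assert net.d == 32

    def test_default_initial_counts(self):
        net = build_niche_model()
        x = net.initial_counts()
        assert x[net.species_index("MET")] == 800
        assert x[net.species_index("EMT")] == 200
        assert x[net.species_index("IL6")] == 1000
        assert x[net.species_index("Lin28")] == 0
        for name in ("gp130", "CXCR1", "HER2", "EGFR", "TGFbR2"):
            assert x[net.species_index(name)] == 100
        for name in ("IL6_gp130", "HER2_EGFR", "act_Stat3", "act_Akt", "act_bcat"):
            assert x[net.species_index(name)] == 0

    def test_overrides(self):
        net = build_niche_model(params={"death_MET": 0.05}, init={"MET": 10})
        assert net.reactions[net.reaction_index("death_MET")].rate_constant == 0.05
        assert net.initial_counts()[net.species_index("MET")] == 10

    def test_unknown_override_rejected(self):
        with pytest.raises(ConfigurationError):
            build_niche_model(params={"no_such_channel": 1.0})
        with pytest.raises(ConfigurationError):
            build_niche_model(init={"no_such_species": 1})

    def test_inhibition_map_covers_nine_targets(self):
        net = build_niche_model()
        mapping = net.metadata["inhibition_map"]
        assert set(mapping) == {
            "IL6", "IL8", "TGFb", "BMP", "mir93", "HER2", "Akt", "Stat3", "Lin28"
        }
        labels = {r.label for r in net.reactions}
        for channels in mapping.values():
            assert channels and set(channels) <= labels


class TestSerialization:
    def test_config_round_trip(self):
        net = build_niche_model()
        cfg = network_to_config(net)
        back = network_from_config(cfg)
        assert back.species_names == net.species_names
        assert [r.label for r in back.reactions] == [r.label for r in net.reactions]
        assert np.array_equal(back.nu, net.nu)
        assert np.allclose(back.rate_constants, net.rate_constants)
        assert back.metadata["inhibition_map"] == net.metadata["inhibition_map"]

    @pytest.mark.parametrize("suffix", [".yaml", ".json", ".xml"])
    def test_file_round_trip(self, tmp_path, suffix):
        net = build_niche_model()
        path = tmp_path / f"net{suffix}"
        save_network(net, path)
        back = load_network(path)
        assert back.species_names == net.species_names
        assert np.array_equal(back.nu, net.nu)
        assert np.allclose(back.rate_constants, net.rate_constants)
        assert np.array_equal(back.initial_counts(), net.initial_counts())
        assert [s.category for s in back.species] == [s.category for s in net.species]

    def test_negative_count_state_rejected(self):
        with pytest.raises(ValueError):
            SystemState(0.0, np.array([1, -1]))
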