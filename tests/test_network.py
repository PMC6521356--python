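"""Network construction, rate laws and conservation structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import her4jakstat as h
from her4jakstat.network import RateLaw, Reaction


class TestCanonicalConstruction:
    def test_two_compartments(self, canonical_net):
        assert len(canonical_net.compartments) == 2
        assert {c.name for c in canonical_net.compartments} == {"cytoplasm", "nucleus"}

    def test_flags_start_off(self, canonical_net):
        assert not canonical_net.heterodimerization_on
        assert not canonical_net.jak_independent_on

    def test_all_rate_law_parameters_resolve(self, canonical_net):
        for rxn in canonical_net.reactions:
            for pid in rxn.rate_law.params.values():
                assert pid in canonical_net.parameters

    def test_core_reactions_present(self, canonical_net):
        ids = {r.id for r in canonical_net.reactions}
        # binding/activation, dimer import, nuclear recycling, SOCS loop,
        # casein transcription/export/degradation
        assert {"R01", "R06", "R12", "R15", "R19", "R20", "R22", "R24",
                "R25", "R28", "R29", "R44", "R45", "R46"} <= ids

    def test_stat5_moiety_in_left_null_space(self, full_net):
        S = h.effective_stoichiometry_matrix(full_net)
        w = h.stat5_moiety_vector(full_net)
        assert np.abs(w @ S).max() == pytest.approx(0.0, abs=1e-12)
        # and the SVD-computed basis spans it
        basis = h.conservation_vectors(full_net)
        proj = basis.T @ (basis @ w)
        assert np.allclose(proj, w, atol=1e-8)

    def test_duplicate_ids_rejected(self, canonical_net):
        bad = canonical_net.copy()
        bad.reactions.append(bad.reactions[0])
        with pytest.raises(ValueError, match="duplicate"):
            bad.validate()


class TestExtensions:
    def test_heterodimerization_adds_three_reactions(self, canonical_net):
        net = h.add_heterodimerization(canonical_net)
        assert len(net.reactions) == len(canonical_net.reactions) + 3
        assert net.heterodimerization_on

    def test_heterodimerization_competes_for_free_her4(self, canonical_net):
        net = h.add_heterodimerization(canonical_net)
        r01 = {s for s, _ in net.reaction_by_id("R01").reactants}
        r41 = {s for s, _ in net.reaction_by_id("R41").reactants}
        assert "HER4" in r01 and "HER4" in r41

    def test_heterodimerization_twice_raises(self, canonical_net):
        net = h.add_heterodimerization(canonical_net)
        with pytest.raises(ValueError, match="already"):
            h.add_heterodimerization(net)

    def test_jak_independent_adds_three_reactions(self, canonical_net):
        net = h.add_jak_independent_branch(canonical_net)
        assert len(net.reactions) == len(canonical_net.reactions) + 3
        assert net.jak_independent_on
        with pytest.raises(ValueError, match="already"):
            h.add_jak_independent_branch(net)

    def test_s80_phosphorylation_slower_than_jak_dependent(self, full_net):
        assert full_net.parameters["kR39"] < full_net.parameters["kR06"]

    def test_socs_feedback_does_not_touch_s80(self, full_net):
        feedback = full_net.reaction_by_id("R28")
        substrates = {s for s, _ in feedback.reactants}
        assert not {"s80", "s80_act"} & substrates


class TestReactionRate:
    def test_bimolecular_mass_action(self):
        rxn = Reaction("X", "x", [("A", 1), ("B", 1)], [("C", 1)],
                       RateLaw("mass_action_irreversible", {"kf": "k"}))
        rate = h.reaction_rate(rxn, {"A": 3.0, "B": 4.0, "C": 0.0}, {"k": 2.0})
        assert rate == pytest.approx(24.0)

    def test_zero_concentration_reactant_gives_zero(self, full_net):
        state = np.zeros(len(full_net.species))
        idx = full_net.species_index
        for rxn in full_net.reactions:
            if rxn.reactants:  # zeroth-order basal production is exempt
                rate = h.reaction_rate(rxn, state, full_net.parameters, idx)
                assert rate == 0.0

    def test_hill_half_saturation(self, full_net):
        rxn = full_net.reaction_by_id("R44")
        p = full_net.parameters
        state = {s.id: 0.0 for s in full_net.species}
        state["STATdim_n"] = p["K_transc"]
        assert h.reaction_rate(rxn, state, p) == pytest.approx(p["V_transc"] / 2)

    def test_negative_state_rejected(self, full_net):
        state = np.zeros(len(full_net.species))
        state[full_net.species_index["STATc"]] = -1.0
        with pytest.raises(ValueError, match="negative"):
            h.reaction_rate(full_net.reaction_by_id("R06"), state,
                            full_net.parameters, full_net.species_index)

    @settings(max_examples=50, deadline=None)
    @given(m=st.floats(min_value=0.0, max_value=1e6, allow_nan=False))
    def test_hill_rate_bounded(self, m):
        rxn = Reaction("T", "t", [], [("G", 1)],
                       RateLaw("hill_activation",
                               {"V_transc": "V", "K_transc": "K", "n_transc": "n"}),
                       modifiers=["M"])
        rate = h.reaction_rate(rxn, {"M": m, "G": 0.0},
                               {"V": 40.0, "K": 100.0, "n": 2.0})
        assert 0.0 <= rate <= 40.0


class TestOdeRhs:
    def test_zero_state_no_sources_is_stationary(self):
        net = h.bench.toy_decay_network()
        rhs = h.ode_rhs(net, np.zeros(2))
        assert np.allclose(rhs, 0.0)

    def test_first_order_decay_rhs(self):
        net = h.bench.toy_decay_network(k1=0.5, k2=0.0, a0=10.0)
        rhs = h.ode_rhs(net, np.array([10.0, 0.0]))
        assert rhs == pytest.approx([-5.0, 5.0])

    def test_stat_moiety_has_zero_net_rate(self, full_net):
        rng = np.random.default_rng(0)
        state = rng.uniform(0.0, 50.0, len(full_net.species))
        rhs = h.ode_rhs(full_net, state)
        w = h.stat5_moiety_vector(full_net)
        vols = full_net.species_volumes()
        assert (w * vols) @ rhs == pytest.approx(0.0, abs=1e-9)

    def test_nan_state_rejected(self, full_net):
        state = np.zeros(len(full_net.species))
        state[0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            h.ode_rhs(full_net, state)

    def test_rhs_matches_compiled_model(self, full_net):
        from her4jakstat.simulate import CompiledModel
        model = CompiledModel(full_net)
        rng = np.random.default_rng(1)
        state = rng.uniform(0.0, 100.0, len(full_net.species))
        p = model.param_vector(full_net.parameters)
        assert np.allclose(model.rhs(0.0, state, p), h.ode_rhs(full_net, state),
                           rtol=1e-12, atol=1e-12)


class TestConfigRoundTrip:
    def test_identity(self, full_net):
        cfg = h.network_to_config(full_net)
        net2 = h.network_from_config(cfg)
        assert [s.id for s in net2.species] == [s.id for s in full_net.species]
        assert [r.id for r in net2.reactions] == [r.id for r in full_net.reactions]
        assert net2.parameters == full_net.parameters
        assert net2.heterodimerization_on and net2.jak_independent_on
        nrg = net2.species_by_id("NRG")
        assert nrg.boundary


def test_competition_flux_non_increasing_in_kfr41(full_net):
    """More favorable heterodimerization drains the HER4-JAK channel."""
    fluxes = []
    for mult in (0.5, 1.0, 2.0, 5.0):
        p = {"kfR41": full_net.parameters["kfR41"] * mult}
        tr = h.run_timecourse(full_net, 20.0, output_step=0.1, params=p)
        pm = dict(full_net.parameters)
        pm.update(p)
        fluxes.append(h.reaction_rate(full_net.reaction_by_id("R03"),
                                      tr.conc[:, -1], pm, full_net.species_index))
    assert all(a >= b for a, b in zip(fluxes, fluxes[1:]))
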