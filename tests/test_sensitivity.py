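"""Network simplification, finite-difference sensitivities, and ranking."""

import networkx as nx
import numpy as np
import pytest

from pdl1net.network import validate_network
from pdl1net.ode import SimulationSettings, simulate
from pdl1net.sensitivity import (
    SensitivityEntry,
    SensitivityReport,
    local_sensitivities,
    rank_parameters,
    simplify_network,
)

from conftest import decay_model, make_model, synthesis_model

SETTINGS = SimulationSettings(
    duration=20.0, n_intervals=100, relative_tolerance=1e-10,
    absolute_tolerance=1e-13,
)


class TestSimplifyNetwork:
    def test_keeping_everything_is_identity(self, reference):
        model = reference.model
        out = simplify_network(model, set(model.species))
        assert out.fingerprint() == model.fingerprint()

    def test_dropping_an_intermediate_removes_adjacent_reactions(self, small_cascade):
        model = small_cascade.model
        # drop one mid-chain kinase: every reaction it touches must go
        victim = "ALK_K1"
        keep = set(model.species) - {victim, f"{victim}_active"}
        out = simplify_network(model, keep)
        for rxn in out.reactions.values():
            assert victim not in rxn.participants()
            assert f"{victim}_active" not in rxn.participants()
        assert len(out.reactions) < len(model.reactions)
        assert validate_network(out) == []

    def test_never_grows_and_matches_graph_closure_oracle(self, reference):
        model = reference.model
        keep = {
            sid for sid in model.species
            if "EGFR" not in sid and sid != "EGF"
        }
        out = simplify_network(model, keep)
        assert len(out.species) <= len(model.species)
        assert len(out.reactions) <= len(model.reactions)

        # independent oracle: bipartite reaction graph; a reaction survives
        # iff all its participant nodes are kept (sinks implicitly kept)
        g = nx.DiGraph()
        kept = keep | model.sink_ids()
        expected_reactions = {
            rid for rid, r in model.reactions.items()
            if all(p in kept for p in r.participants())
        }
        assert set(out.reactions) == expected_reactions
        for rid in expected_reactions:
            for p in model.reactions[rid].participants():
                g.add_edge(rid, p)
        expected_species = set(keep) | {
            p for rid in expected_reactions
            for p in model.reactions[rid].participants()
        }
        assert set(out.species) == expected_species & set(model.species)

    def test_excluding_the_readout_is_an_error(self, reference):
        model = reference.model
        with pytest.raises(ValueError, match="output species"):
            simplify_network(model, set(model.species) - {model.output_species})


class TestLocalSensitivities:
    def test_disconnected_parameter_has_zero_sensitivity(self):
        m = decay_model(k=0.3)
        # an isolated side reaction with no path to the readout
        from pdl1net.network import KineticLaw, Reaction, Species

        m.add_species(Species(id="P", initial_concentration=1.0))
        m.add_species(Species(id="Q"))
        m.add_reaction(
            Reaction(
                id="side",
                substrates=[("P", 1)],
                products=[("Q", 1)],
                law=KineticLaw.mass_action(0.7),
            )
        )
        report = local_sensitivities(m, "A", SETTINGS)
        by_key = {(e.reaction_id, e.parameter): e.value for e in report.entries}
        assert by_key[("side", "k1")] == pytest.approx(0.0, abs=1e-8)
        assert by_key[("A_degradation", "k1")] != pytest.approx(0.0, abs=1e-6)

    def test_pure_synthesis_sensitivity_equals_duration(self):
        # c(T) = k·T, so dc/dk = T exactly
        T = 20.0
        report = local_sensitivities(synthesis_model(k=0.3), "X", SETTINGS)
        (entry,) = [e for e in report.entries if e.reaction_id == "X_synthesis"]
        assert entry.value == pytest.approx(T, rel=1e-6)

    def test_scaled_synthesis_sensitivity_is_scale_free(self):
        # scaled form: (dc/dk)·(k/c) = T·k/(k·T) = 1 for any k
        for k in (0.05, 0.3, 2.0):
            report = local_sensitivities(
                synthesis_model(k=k), "X", SETTINGS, scaling="scaled"
            )
            (entry,) = [e for e in report.entries if e.reaction_id == "X_synthesis"]
            assert entry.value == pytest.approx(1.0, rel=1e-6)

    def test_signs_match_brute_force_resimulation(self, small_cascade):
        model = small_cascade.model
        settings = SimulationSettings(
            duration=30.0, n_intervals=60, relative_tolerance=1e-10,
            absolute_tolerance=1e-13,
        )
        target = model.output_species
        report = local_sensitivities(model, target, settings, delta=0.01)
        baseline = simulate(model, settings).endpoint(target)
        for entry in report.entries:
            if entry.failed or abs(entry.value) < 1e-9:
                continue
            # oracle: +10% perturbation, direct re-simulation
            perturbed = model.copy()
            rxn = perturbed.reactions[entry.reaction_id]
            p0 = dict(rxn.law.parameter_items())[entry.parameter]
            rxn.law = rxn.law.with_parameter(entry.parameter, p0 * 1.1)
            moved = simulate(perturbed, settings).endpoint(target)
            assert np.sign(moved - baseline) == np.sign(entry.value), (
                entry.reaction_id, entry.parameter,
            )

    def test_delta_halving_convergence(self, small_cascade):
        model = small_cascade.model
        settings = SimulationSettings(
            duration=30.0, n_intervals=60, relative_tolerance=1e-10,
            absolute_tolerance=1e-13,
        )
        target = model.output_species
        coarse = local_sensitivities(model, target, settings, delta=1e-2)
        fine = local_sensitivities(model, target, settings, delta=5e-3)
        scale = max(abs(e.value) for e in coarse.entries if e.value is not None)
        for a, b in zip(coarse.entries, fine.entries):
            assert (a.reaction_id, a.parameter) == (b.reaction_id, b.parameter)
            if abs(a.value) < 1e-6 * scale:
                continue  # numerically zero entries carry no signal
            assert b.value == pytest.approx(a.value, rel=0.05)


class TestRankParameters:
    def _report(self, entries):
        return SensitivityReport(entries=entries, target="X", scaling="unscaled")

    def test_sorts_by_magnitude(self):
        entries = [
            SensitivityEntry("r1", "k1", 3.0),
            SensitivityEntry("r2", "k1", -1.0),
            SensitivityEntry("r3", "Km", -2.0),
        ]
        ranked = rank_parameters(self._report(entries))
        assert [e.value for e in ranked] == [3.0, -2.0, -1.0]

    def test_ties_break_lexicographically(self):
        entries = [
            SensitivityEntry("rB", "k1", 1.0),
            SensitivityEntry("rA", "k1", -1.0),
            SensitivityEntry("rA", "Kcat", 1.0),
        ]
        ranked = rank_parameters(self._report(entries))
        assert [(e.reaction_id, e.parameter) for e in ranked] == [
            ("rA", "Kcat"),
            ("rA", "k1"),
            ("rB", "k1"),
        ]

    def test_top_n_truncates(self):
        entries = [SensitivityEntry(f"r{i}", "k1", float(i)) for i in range(5)]
        assert len(rank_parameters(self._report(entries), top_n=2)) == 2
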