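"""ODE assembly, LSODA simulation, summaries, and steady states, checked
against closed forms and an independent fixed-step RK4 integrator."""

import math

import numpy as np
import pytest

from pdl1net.network import (
    InvalidModelError,
    KineticLaw,
    Reaction,
    Species,
)
from pdl1net.ode import (
    SimulationError,
    SimulationSettings,
    auc,
    build_ode_system,
    find_plateau,
    simulate,
    steady_state,
)

from conftest import (
    decay_model,
    fleet,
    make_model,
    reversible_pair_model,
    rk4_endpoint,
    synthesis_model,
)


class TestSettings:
    def test_interval_size_drives_interval_count(self):
        s = SimulationSettings(duration=10.0, interval_size=0.1)
        assert s.n_intervals == 100
        assert len(s.times()) == 101

    def test_inconsistent_triple_warns_and_derives(self):
        # a stated count inconsistent with duration/interval_size is overridden
        with pytest.warns(UserWarning, match="inconsistent"):
            s = SimulationSettings(
                duration=2e5, interval_size=4.656609941, n_intervals=429497
            )
        assert s.n_intervals == round(2e5 / 4.656609941)

    def test_tiny_max_internal_steps_warns(self):
        with pytest.warns(UserWarning, match="max_internal_steps"):
            SimulationSettings(duration=1.0, max_internal_steps=10)


class TestBuildSystem:
    def test_single_degradation_derivative(self):
        rhs, index = build_ode_system(decay_model(k=0.5))
        y = np.zeros(len(index))
        y[index["A"]] = 2.0
        assert rhs(0.0, y)[index["A"]] == pytest.approx(-1.0)

    def test_disconnected_species_has_zero_derivative(self):
        m = decay_model()
        m.add_species(Species(id="lonely", initial_concentration=3.0))
        rhs, index = build_ode_system(m)
        y = np.full(len(index), 2.0)
        assert rhs(0.0, y)[index["lonely"]] == 0.0

    def test_drug_inactivation_subsystem_derivatives(self):
        # modifier-scaled MM consumption of the target plus first-order drug
        # decay: d[target]/dt = −Kcat·c·a/(Km+a), d[drug]/dt = −k1·c
        Kcat, Km, k1 = 2.0, 0.7, 0.4
        m = make_model(
            [
                Species(id="ALK_Mutated", initial_concentration=1.0),
                Species(id="Crizotinib", role="drug", initial_concentration=1.0),
                Species(id="sink", role="sink"),
            ],
            [
                Reaction(
                    id="inactivation",
                    substrates=[("ALK_Mutated", 1)],
                    products=[("sink", 1)],
                    modifiers=["Crizotinib"],
                    law=KineticLaw.modified_hmm(Kcat, Km, "Crizotinib"),
                ),
                Reaction(
                    id="drug_decay",
                    substrates=[("Crizotinib", 1)],
                    products=[("sink", 1)],
                    law=KineticLaw.mass_action(k1),
                    category="degradation",
                ),
            ],
        )
        rhs, index = build_ode_system(m)
        c, a = 0.8, 0.6
        y = np.zeros(len(index))
        y[index["Crizotinib"]], y[index["ALK_Mutated"]] = c, a
        dy = rhs(0.0, y)
        assert dy[index["ALK_Mutated"]] == pytest.approx(-Kcat * c * a / (Km + a))
        assert dy[index["Crizotinib"]] == pytest.approx(-k1 * c)

    def test_invalid_model_is_rejected_with_violations(self):
        m = decay_model()
        m.species["A"].initial_concentration = -1.0
        with pytest.raises(InvalidModelError, match="A"):
            build_ode_system(m)


class TestSimulate:
    def test_exponential_decay_endpoint(self):
        traj = simulate(
            decay_model(k=math.log(2)),
            SimulationSettings(duration=1.0, n_intervals=100,
                               relative_tolerance=1e-9),
        )
        assert traj.endpoint("A") == pytest.approx(0.5, rel=1e-6)

    def test_first_sample_is_the_initial_state(self, reference, reference_settings):
        traj = simulate(reference.model, reference_settings)
        initial = reference.model.initial_state()
        for sid in traj.species_order:
            assert traj.concentration(sid)[0] == pytest.approx(initial[sid])

    @pytest.mark.parametrize(
        "name, model, settings", fleet(), ids=[f[0] for f in fleet()]
    )
    def test_endpoint_matches_rk4_oracle(self, name, model, settings):
        traj = simulate(model, settings)
        y_rk4, index = rk4_endpoint(model, settings.duration, n_steps=10_000)
        scale = max(1e-12, float(np.abs(y_rk4).max()))
        for sid, i in index.items():
            assert traj.endpoint(sid) == pytest.approx(
                max(y_rk4[i], 0.0), rel=1e-4, abs=1e-4 * scale
            )

    def test_step_exhaustion_reports_last_time(self):
        with pytest.warns(UserWarning):
            settings = SimulationSettings(
                duration=1e5, n_intervals=2, max_internal_steps=5
            )
        with pytest.raises(SimulationError) as err:
            simulate(decay_model(k=50.0), settings)
        assert 0.0 <= err.value.last_time < 1e5

    def test_volume_invariance(self):
        # concentration dynamics are unchanged when the compartment volume is
        # scaled: V cancels from d([X]·V)/dt = ±V·rate
        settings = SimulationSettings(duration=1.0, n_intervals=50)
        t1 = simulate(decay_model(), settings)
        m10 = decay_model()
        m10.compartments["cytoplasm"].volume = 10.0
        t10 = simulate(m10, settings)
        np.testing.assert_allclose(t1.values, t10.values, rtol=1e-12)

    def test_conservation_of_interconverting_pairs(self, reference):
        settings = SimulationSettings(
            duration=100.0, n_intervals=100,
            relative_tolerance=1e-8, absolute_tolerance=1e-8,
        )
        traj = simulate(reference.model, settings)
        pairs = {
            tuple(sorted((sp.id, sp.counterpart)))
            for sp in reference.model.species.values()
            if sp.counterpart is not None
        }
        for a, b in pairs:
            total = traj.concentration(a) + traj.concentration(b)
            drift = np.abs(total - total[0]).max()
            assert drift <= 10 * settings.absolute_tolerance

    def test_non_negativity_on_fleet(self):
        for name, model, settings in fleet():
            traj = simulate(model, settings)
            assert traj.values.min() >= 0.0, name
            assert traj.diagnostics["min_value"] >= -1e-8, name

    def test_refinement_stability(self):
        # halving the interval size must not move endpoints: output times do
        # not steer LSODA's step control
        for name, model, settings in fleet():
            tight = SimulationSettings(
                duration=settings.duration,
                n_intervals=settings.n_intervals,
                relative_tolerance=1e-10,
                absolute_tolerance=1e-14,
            )
            halved = SimulationSettings(
                duration=settings.duration,
                n_intervals=2 * settings.n_intervals,
                relative_tolerance=1e-10,
                absolute_tolerance=1e-14,
            )
            a = simulate(model, tight).values[:, -1]
            b = simulate(model, halved).values[:, -1]
            scale = max(np.abs(a).max(), 1e-12)
            assert np.abs(a - b).max() / scale < 1e-6, name


class TestSummaries:
    def test_auc_rectangle_and_triangle(self):
        const = simulate(
            make_model([Species(id="C", initial_concentration=2.0)], [], output="C"),
            SimulationSettings(duration=10.0, n_intervals=10),
        )
        assert auc(const, "C") == pytest.approx(20.0)
        ramp = simulate(
            synthesis_model(k=2.0), SimulationSettings(duration=2.0, n_intervals=20)
        )
        assert auc(ramp, "X") == pytest.approx(4.0, rel=1e-6)

    def test_auc_of_exponential_decay(self):
        traj = simulate(
            decay_model(k=math.log(2)),
            SimulationSettings(duration=1.0, n_intervals=400,
                               relative_tolerance=1e-9),
        )
        assert auc(traj, "A") == pytest.approx((1 - 0.5) / math.log(2), rel=1e-3)

    def test_auc_unknown_species(self):
        traj = simulate(decay_model(), SimulationSettings(duration=1.0))
        with pytest.raises(KeyError):
            auc(traj, "ghost")

    def test_plateau_constant_linear_and_saturating(self):
        const = simulate(
            make_model([Species(id="C", initial_concentration=2.0)], [], output="C"),
            SimulationSettings(duration=10.0, n_intervals=10),
        )
        assert find_plateau(const, "C") == 0.0

        linear = simulate(
            synthesis_model(k=1.0), SimulationSettings(duration=10.0, n_intervals=50)
        )
        assert find_plateau(linear, "X") is None

        # c(t) = 1 − e^(−t): slope falls below 1% of its max near t = ln 100
        saturating = simulate(
            make_model(
                [
                    Species(id="P", initial_concentration=1.0),
                    Species(id="Q", initial_concentration=0.0),
                ],
                [
                    Reaction(
                        id="conv",
                        substrates=[("P", 1)],
                        products=[("Q", 1)],
                        law=KineticLaw.mass_action(1.0),
                    )
                ],
            ),
            SimulationSettings(duration=10.0, n_intervals=200),
        )
        t = find_plateau(saturating, "Q", rel_slope_threshold=0.01)
        assert t is not None and math.log(100) <= t <= 10.0


class TestSteadyState:
    def test_symmetric_reversible_pair(self):
        result = steady_state(reversible_pair_model(), max_time=1e3)
        assert result.success
        assert result.state["A"] == pytest.approx(1.0, abs=1e-6)
        assert result.state["B"] == pytest.approx(1.0, abs=1e-6)

    def test_pure_degradation_exhausts(self):
        result = steady_state(decay_model(), max_time=1e3, tolerance=1e-9)
        assert result.success
        assert result.state["A"] == pytest.approx(0.0, abs=1e-6)

    def test_constitutive_source_matches_long_integration(self):
        # source feeding the readout through degradation-balanced turnover
        m = make_model(
            [
                Species(id="PDL1_mRNA", role="mRNA"),
                Species(id="sink", role="sink"),
            ],
            [
                Reaction(
                    id="synthesis",
                    products=[("PDL1_mRNA", 1)],
                    law=KineticLaw.mass_action(0.4),
                ),
                Reaction(
                    id="turnover",
                    substrates=[("PDL1_mRNA", 1)],
                    products=[("sink", 1)],
                    law=KineticLaw.mass_action(0.1),
                    category="degradation",
                ),
            ],
            output="PDL1_mRNA",
        )
        result = steady_state(m, max_time=1e3, tolerance=1e-8)
        assert result.success
        long = simulate(
            m, SimulationSettings(duration=1e4, n_intervals=100)
        ).endpoint("PDL1_mRNA")
        assert result.state["PDL1_mRNA"] == pytest.approx(long, rel=1e-6)
        assert result.state["PDL1_mRNA"] == pytest.approx(4.0, rel=1e-6)

    def test_sustained_growth_reports_failure(self):
        result = steady_state(synthesis_model(k=1.0), max_time=100.0)
        assert not result.success
        assert result.state is None
        assert "no steady state" in result.message
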