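"""Shared fixtures: a fleet of small analytically tractable models plus the
frozen reference cascade, and an independent fixed-step RK4 integrator used
as an oracle against the LSODA engine."""

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pdl1net.network import (
    Compartment,
    KineticLaw,
    NetworkModel,
    Reaction,
    Species,
)
from pdl1net.ode import SimulationSettings, build_ode_system
from pdl1net.synth import (
    REFERENCE_SETTINGS,
    CascadeSpec,
    generate_cascade_network,
    reference_cascade,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_model(species, reactions, output=None, volume=1.0):
    """Terse single-compartment model builder for tests."""
    m = NetworkModel(output_species=output)
    m.add_compartment(Compartment(id="cytoplasm", volume=volume))
    for sp in species:
        m.add_species(sp)
    for r in reactions:
        m.add_reaction(r)
    return m


def decay_model(k=math.log(2), a0=1.0):
    """A →(k) Ø; closed form A(t) = a0·e^(−k t)."""
    return make_model(
        [
            Species(id="A", initial_concentration=a0),
            Species(id="sink", role="sink"),
        ],
        [
            Reaction(
                id="A_degradation",
                substrates=[("A", 1)],
                products=[("sink", 1)],
                law=KineticLaw.mass_action(k),
                category="degradation",
            )
        ],
        output="A",
    )


def reversible_pair_model(k1=1.0, k2=1.0, a0=2.0, b0=0.0):
    """A ⇌ B mass action; symmetric constants give steady state A=B."""
    return make_model(
        [
            Species(id="A", initial_concentration=a0),
            Species(id="B", initial_concentration=b0),
        ],
        [
            Reaction(
                id="interconversion",
                substrates=[("A", 1)],
                products=[("B", 1)],
                law=KineticLaw.mass_action(k1, k2),
            )
        ],
        output="B",
    )


def synthesis_model(k=0.3):
    """Ø →(k) X constitutive synthesis; closed form X(t) = k·t."""
    return make_model(
        [Species(id="X"), Species(id="sink", role="sink")],
        [
            Reaction(
                id="X_synthesis",
                products=[("X", 1)],
                law=KineticLaw.mass_action(k),
            )
        ],
        output="X",
    )


SMALL_CASCADE_SPEC = CascadeSpec(
    n_layers=2, include_egfr_branch=False, seed=7
)


@pytest.fixture(scope="session")
def small_cascade():
    return generate_cascade_network(SMALL_CASCADE_SPEC)


@pytest.fixture(scope="session")
def reference():
    return reference_cascade()


@pytest.fixture(scope="session")
def reference_settings():
    return REFERENCE_SETTINGS


def fleet():
    """(model, settings) pairs covering the behaviors the engine must honor."""
    ref_model, _ = reference_cascade()
    small_model, _ = generate_cascade_network(SMALL_CASCADE_SPEC)
    s = lambda d: SimulationSettings(
        duration=d, n_intervals=200, relative_tolerance=1e-8,
        absolute_tolerance=1e-12,
    )
    return [
        ("decay", decay_model(), s(1.0)),
        ("reversible", reversible_pair_model(), s(10.0)),
        ("synthesis", synthesis_model(), s(10.0)),
        ("small_cascade", small_model, s(50.0)),
        ("reference_cascade", ref_model, REFERENCE_SETTINGS),
    ]


def rk4_endpoint(model, duration, n_steps):
    """Classic fixed-step 4th-order Runge–Kutta endpoint — an integrator
    independent of the LSODA path (shares only the compiled RHS)."""
    rhs, index = build_ode_system(model)
    y = np.array(
        [model.species[sid].initial_concentration for sid in index], dtype=float
    )
    h = duration / n_steps
    t = 0.0
    for _ in range(n_steps):
        k1 = rhs(t, y)
        k2 = rhs(t + h / 2, y + h / 2 * k1)
        k3 = rhs(t + h / 2, y + h / 2 * k2)
        k4 = rhs(t + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    return y, index
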