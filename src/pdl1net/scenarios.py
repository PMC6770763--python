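"""Experimental arms by programmatic model surgery.

The four classic arms are wild-type vs ALK-F1174L, each optionally treated
with crizotinib (ALK inhibitor), gefitinib (EGFR inhibitor), or both:

* the activating F1174L mutation is modeled as a constitutively active
  ``ALK_Mutated`` species present at nonzero initial concentration and
  driving the same downstream reactions as ligand-activated ALK;
* crizotinib enters as a drug species at its dose, inactivating
  ``ALK_Mutated`` through a modifier-scaled Michaelis–Menten reaction
  (the drug is the modifier, the mutant kinase the substrate) and decaying
  by first-order mass action;
* gefitinib analogously converts ``EGFR_free`` to an inhibited form and
  decays first-order.

All surgery functions are pure: they deep-copy their input and never mutate
it.  Drug kinetic constants are configuration with documented defaults; a
model imported with embedded drug mechanics keeps its own values.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import KineticLaw, NetworkModel, Reaction, Species
from .ode import SimulationSettings, SimulationError, Trajectory, auc, simulate

__all__ = [
    "DrugParameters",
    "CRIZOTINIB_DEFAULTS",
    "GEFITINIB_DEFAULTS",
    "Scenario",
    "ArmComparison",
    "apply_alk_mutation",
    "apply_crizotinib",
    "apply_gefitinib",
    "build_scenario_model",
    "run_arms",
]

ALK_ACTIVE_ID = "ALK_active"
ALK_INACTIVE_ID = "ALK"
ALK_MUTATED_ID = "ALK_Mutated"
EGFR_FREE_ID = "EGFR_free"
EGFR_INHIBITED_ID = "EGFR_inhibited"
CRIZOTINIB_ID = "Crizotinib"
GEFITINIB_ID = "Gefitinib"

#: Paper-style doses, mM (= mmol/mL nominal units of the engine).
CRIZOTINIB_DOSE = 1.4e-3
GEFITINIB_DOSE = 3.0e-3


@dataclass(frozen=True)
class DrugParameters:
    """Kinetics of a drug intervention: modifier-scaled MM inactivation of
    its target (``kcat``, ``km``) plus first-order drug decay (``k_deg``)."""

    kcat: float
    km: float
    k_deg: float


# Defaults sized so the standard doses above act on an O(1 mmol/mL) target
# pool within the reference time course: kcat·dose sets the inactivation
# speed (~0.5/s for crizotinib at 1.4e-3 mM), and drug decay is slow enough
# that the drug persists through the run.
CRIZOTINIB_DEFAULTS = DrugParameters(kcat=500.0, km=0.5, k_deg=1e-3)
GEFITINIB_DEFAULTS = DrugParameters(kcat=500.0, km=0.5, k_deg=1e-3)


class StructuralError(ValueError):
    """The model lacks a species the intervention needs."""


def _require(model: NetworkModel, species_id: str, why: str) -> None:
    if species_id not in model.species:
        raise StructuralError(f"model has no {species_id!r} species; {why}")


def _sink_id(model: NetworkModel) -> str:
    sinks = sorted(model.sink_ids())
    if not sinks:
        raise StructuralError("model has no sink species for degradation products")
    return sinks[0]


def apply_alk_mutation(
    model: NetworkModel, initial_concentration: float | None = None
) -> NetworkModel:
    """Return a copy carrying the constitutively active ALK mutant.

    ``ALK_Mutated`` is added at nonzero initial concentration (default: the
    wild-type inactive ALK pool size) and, for every reaction in which
    active ALK acts as a modifier, a parallel reaction driven by the mutant
    is added with identical kinetics.  The mutant has no deactivation
    reaction — its activity is constitutive; it is only consumed if an
    inhibitor is applied.  Idempotent: a model already carrying the mutant
    is returned as an unmodified copy.
    """
    out = model.copy()
    if ALK_MUTATED_ID in out.species:
        return out
    _require(out, ALK_ACTIVE_ID, "cannot graft the mutation without an ALK node")
    alk_active = out.species[ALK_ACTIVE_ID]
    if initial_concentration is None:
        wt = out.species.get(ALK_INACTIVE_ID)
        initial_concentration = wt.initial_concentration if wt else 1.0
    if initial_concentration <= 0:
        raise ValueError("the mutant must start at a nonzero concentration")

    out.add_species(
        Species(
            id=ALK_MUTATED_ID,
            name="ALK F1174L (constitutively active)",
            compartment=alk_active.compartment,
            role="protein",
            activation_state="active",
            initial_concentration=initial_concentration,
            initial_overridden=True,
        )
    )
    for rxn in list(model.reactions.values()):
        if ALK_ACTIVE_ID in rxn.modifiers:
            clone = copy.deepcopy(rxn)
            clone.id = f"{rxn.id}__by_{ALK_MUTATED_ID}"
            clone.name = f"{rxn.name or rxn.id} (mutant ALK driven)"
            clone.modifiers = [
                ALK_MUTATED_ID if m == ALK_ACTIVE_ID else m for m in rxn.modifiers
            ]
            if clone.law.modifier == ALK_ACTIVE_ID:
                clone.law.modifier = ALK_MUTATED_ID
            if clone.law.enzyme == ALK_ACTIVE_ID:
                clone.law.enzyme = ALK_MUTATED_ID
            out.add_reaction(clone)
    return out


def apply_crizotinib(
    model: NetworkModel,
    dose_mM: float,
    params: DrugParameters = CRIZOTINIB_DEFAULTS,
) -> NetworkModel:
    """Add crizotinib at ``dose_mM``: one drug species and two reactions
    (modifier-scaled MM inactivation of the ALK mutant, first-order drug
    degradation).  Dose 0 adds the inert machinery without effect."""
    if dose_mM < 0:
        raise ValueError("dose must be >= 0")
    out = model.copy()
    target = ALK_MUTATED_ID if ALK_MUTATED_ID in out.species else ALK_ACTIVE_ID
    _require(out, target, "crizotinib needs an active ALK species to inhibit")
    sink = _sink_id(out)
    out.add_species(
        Species(
            id=CRIZOTINIB_ID,
            name="Crizotinib",
            compartment=out.species[target].compartment,
            role="drug",
            initial_concentration=dose_mM,
        )
    )
    out.add_reaction(
        Reaction(
            id=f"{target}_inactivation_by_crizotinib",
            substrates=[(target, 1)],
            products=[(sink, 1)],
            modifiers=[CRIZOTINIB_ID],
            law=KineticLaw.modified_hmm(params.kcat, params.km, CRIZOTINIB_ID),
            category="activation/inhibition",
        )
    )
    out.add_reaction(
        Reaction(
            id="Crizotinib_degradation",
            substrates=[(CRIZOTINIB_ID, 1)],
            products=[(sink, 1)],
            law=KineticLaw.mass_action(params.k_deg),
            category="degradation",
        )
    )
    return out


def apply_gefitinib(
    model: NetworkModel,
    dose_mM: float,
    params: DrugParameters = GEFITINIB_DEFAULTS,
) -> NetworkModel:
    """Add gefitinib at ``dose_mM``: the drug species, an inhibited-EGFR
    species (if absent), an inhibition reaction (drug as modifier) and
    first-order drug degradation."""
    if dose_mM < 0:
        raise ValueError("dose must be >= 0")
    out = model.copy()
    _require(out, EGFR_FREE_ID, "gefitinib needs a free-EGFR species to inhibit")
    sink = _sink_id(out)
    comp = out.species[EGFR_FREE_ID].compartment
    out.add_species(
        Species(
            id=GEFITINIB_ID,
            name="Gefitinib",
            compartment=comp,
            role="drug",
            initial_concentration=dose_mM,
        )
    )
    if EGFR_INHIBITED_ID not in out.species:
        out.add_species(
            Species(
                id=EGFR_INHIBITED_ID,
                name="EGFR (gefitinib-inhibited)",
                compartment=comp,
                role="protein",
                activation_state="not_applicable",
            )
        )
    out.add_reaction(
        Reaction(
            id="EGFR_inhibition_by_gefitinib",
            substrates=[(EGFR_FREE_ID, 1)],
            products=[(EGFR_INHIBITED_ID, 1)],
            modifiers=[GEFITINIB_ID],
            law=KineticLaw.modified_hmm(params.kcat, params.km, GEFITINIB_ID),
            category="activation/inhibition",
        )
    )
    out.add_reaction(
        Reaction(
            id="Gefitinib_degradation",
            substrates=[(GEFITINIB_ID, 1)],
            products=[(sink, 1)],
            law=KineticLaw.mass_action(params.k_deg),
            category="degradation",
        )
    )
    return out


@dataclass(frozen=True)
class Scenario:
    """One experimental arm: mutation flag, ligand stimulation, drug doses,
    and optional initial-concentration overrides applied last."""

    label: str
    alk_f1174l: bool = False
    stimulations: dict[str, float] = field(default_factory=dict)  # ligand id -> dose
    crizotinib_dose: float = 0.0
    gefitinib_dose: float = 0.0
    overrides: dict[str, float] = field(default_factory=dict)
    crizotinib_params: DrugParameters = CRIZOTINIB_DEFAULTS
    gefitinib_params: DrugParameters = GEFITINIB_DEFAULTS

    def __post_init__(self) -> None:
        if self.crizotinib_dose < 0 or self.gefitinib_dose < 0:
            raise ValueError("doses must be >= 0")


def build_scenario_model(base: NetworkModel, scenario: Scenario) -> NetworkModel:
    """Apply a scenario's surgery steps to a copy of the base model."""
    model = base.copy()
    if scenario.alk_f1174l:
        model = apply_alk_mutation(model)
    if scenario.crizotinib_dose > 0:
        model = apply_crizotinib(
            model, scenario.crizotinib_dose, scenario.crizotinib_params
        )
    if scenario.gefitinib_dose > 0:
        model = apply_gefitinib(
            model, scenario.gefitinib_dose, scenario.gefitinib_params
        )
    for sid, conc in {**scenario.stimulations, **scenario.overrides}.items():
        if sid not in model.species:
            raise StructuralError(f"override targets unknown species {sid!r}")
        sp = model.species[sid]
        sp.initial_concentration = conc
        sp.initial_overridden = True
    return model


@dataclass
class ArmComparison:
    """Per-arm readout summary: endpoint concentration and AUC of the
    output species, plus the trajectory itself (None on failure)."""

    table: pd.DataFrame  # columns: arm, endpoint, auc, error
    trajectories: dict[str, Trajectory | None]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def run_arms(
    base: NetworkModel,
    scenarios: list[Scenario],
    settings: SimulationSettings,
    output_species: str | None = None,
) -> ArmComparison:
    """Simulate every arm with identical settings and summarize the readout.

    Arms are independent (each gets a fresh copy of the base model); a
    failed integration is reported in the ``error`` column without aborting
    the other arms.
    """
    labels = [s.label for s in scenarios]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate arm labels")
    readout = output_species or base.output_species
    if readout is None:
        raise ValueError("no output species designated")

    rows, trajectories = [], {}
    for scenario in scenarios:
        model = build_scenario_model(base, scenario)
        try:
            traj = simulate(model, settings)
        except SimulationError as exc:
            rows.append((scenario.label, np.nan, np.nan, str(exc)))
            trajectories[scenario.label] = None
            continue
        rows.append(
            (scenario.label, traj.endpoint(readout), auc(traj, readout), "")
        )
        trajectories[scenario.label] = traj
    table = pd.DataFrame(rows, columns=["arm", "endpoint", "auc", "error"])
    return ArmComparison(table=table, trajectories=trajectories)
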