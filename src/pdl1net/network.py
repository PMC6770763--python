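"""Core domain types for signaling reaction networks.

A :class:`NetworkModel` is a collection of compartments, species and
reactions, each reaction carrying one of three kinetic-law variants:

* **mass action** — rate ``k1·∏[substrates] − k2·∏[products]``, used for
  degradation and simple conversions (drug decay is first-order mass action);
* **Henri–Michaelis–Menten (HMM)** — rate ``Kcat·E·S/(Km+S)`` for enzymatic
  steps such as transcription and translation; when no enzyme species is
  referenced, ``Kcat`` plays the role of ``Vmax`` (E ≡ 1);
* **modified HMM** — rate ``Kcat·M·S/(Km+S)``, linear in the concentration
  ``M`` of a modifier species; this is the form used for drug-mediated
  inactivation (an inhibitor is the *modifier* of a reaction that converts
  its target to an inactive species).

Imported models may additionally carry *opaque* rate laws: an arbitrary
symbolic expression over species and numeric parameters, kept verbatim and
evaluated symbolically.

Concentrations are nominally mmol/mL and time is in seconds; the engine is
unit-agnostic and these labels are carried only in metadata.
"""

from __future__ import annotations

import copy
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ROLES",
    "ACTIVATION_STATES",
    "CATEGORIES",
    "Compartment",
    "Species",
    "KineticLaw",
    "Reaction",
    "NetworkModel",
    "mass_action_rate",
    "hmm_rate",
    "modified_hmm_rate",
    "validate_network",
    "InvalidModelError",
]

ROLES = ("gene", "mRNA", "protein", "simple molecule", "drug", "sink")
ACTIVATION_STATES = ("inactive", "active", "not_applicable")
CATEGORIES = (
    "post-translational modification",
    "activation/inhibition",
    "degradation",
    "transcription",
    "translation",
)

#: Law variant tags.
MASS_ACTION = "MassAction"
HMM = "HMM"
MODIFIED_HMM = "ModifiedHMM"
OPAQUE = "Opaque"


class InvalidModelError(ValueError):
    """Raised when an operation requires a model that fails validation."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__(
            "model failed validation:\n" + "\n".join(f"  - {v}" for v in violations)
        )


@dataclass
class Compartment:
    id: str
    name: str = ""
    volume: float = 1.0  # nominal mL; must be > 0


@dataclass
class Species:
    """One molecular node.

    ``counterpart`` links an inactive form to its active form (and is the id
    of the *other* member of the pair).  Active species with a counterpart
    start at concentration zero unless ``initial_overridden`` is set by a
    scenario.
    """

    id: str
    name: str = ""
    compartment: str = "cytoplasm"
    role: str = "protein"
    activation_state: str = "not_applicable"
    initial_concentration: float = 0.0  # nominal mmol/mL
    counterpart: str | None = None
    initial_overridden: bool = False


@dataclass
class KineticLaw:
    """Tagged union over the supported rate-law variants.

    Only the fields belonging to ``variant`` are meaningful; the
    constructors below are the intended way to build instances.
    """

    variant: str
    k1: float | None = None
    k2: float | None = None
    Kcat: float | None = None
    Km: float | None = None
    enzyme: str | None = None  # species id, HMM only
    modifier: str | None = None  # species id, ModifiedHMM only
    expression: str | None = None  # Opaque only: symbolic rate over species ids
    parameters: dict[str, float] = field(default_factory=dict)

    @classmethod
    def mass_action(cls, k1: float, k2: float | None = None) -> "KineticLaw":
        if k1 < 0 or (k2 is not None and k2 < 0):
            raise ValueError("mass-action rate constants must be non-negative")
        return cls(variant=MASS_ACTION, k1=k1, k2=k2)

    @classmethod
    def hmm(cls, Kcat: float, Km: float, enzyme: str | None = None) -> "KineticLaw":
        if Km <= 0:
            raise ValueError("Km must be strictly positive")
        if Kcat < 0:
            raise ValueError("Kcat must be non-negative")
        return cls(variant=HMM, Kcat=Kcat, Km=Km, enzyme=enzyme)

    @classmethod
    def modified_hmm(cls, Kcat: float, Km: float, modifier: str) -> "KineticLaw":
        if Km <= 0:
            raise ValueError("Km must be strictly positive")
        if Kcat < 0:
            raise ValueError("Kcat must be non-negative")
        return cls(variant=MODIFIED_HMM, Kcat=Kcat, Km=Km, modifier=modifier)

    @classmethod
    def opaque(
        cls, expression: str, parameters: Mapping[str, float] | None = None
    ) -> "KineticLaw":
        return cls(
            variant=OPAQUE, expression=expression, parameters=dict(parameters or {})
        )

    def parameter_items(self) -> list[tuple[str, float]]:
        """(name, value) pairs of the numeric constants this law carries."""
        if self.variant == MASS_ACTION:
            out = [("k1", self.k1)]
            if self.k2 is not None:
                out.append(("k2", self.k2))
            return out
        if self.variant in (HMM, MODIFIED_HMM):
            return [("Kcat", self.Kcat), ("Km", self.Km)]
        return sorted(self.parameters.items())

    def with_parameter(self, name: str, value: float) -> "KineticLaw":
        law = copy.deepcopy(self)
        if law.variant == OPAQUE:
            if name not in law.parameters:
                raise KeyError(name)
            law.parameters[name] = value
        elif name in ("k1", "k2", "Kcat", "Km"):
            setattr(law, name, value)
        else:
            raise KeyError(name)
        return law


@dataclass
class Reaction:
    id: str
    substrates: list[tuple[str, int]] = field(default_factory=list)
    products: list[tuple[str, int]] = field(default_factory=list)
    modifiers: list[str] = field(default_factory=list)
    law: KineticLaw = field(default_factory=lambda: KineticLaw.mass_action(0.0))
    category: str = "activation/inhibition"
    citations: list[str] = field(default_factory=list)  # PubMed ids, annotation only
    name: str = ""

    def participants(self) -> set[str]:
        ids = {s for s, _ in self.substrates} | {p for p, _ in self.products}
        ids |= set(self.modifiers)
        if self.law.enzyme:
            ids.add(self.law.enzyme)
        if self.law.modifier:
            ids.add(self.law.modifier)
        return ids


@dataclass
class NetworkModel:
    """In-memory reaction network with a designated readout node.

    Species, compartments and reactions are stored in insertion-ordered
    mappings keyed by id; reactions reference species by id.
    """

    compartments: dict[str, Compartment] = field(default_factory=dict)
    species: dict[str, Species] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    output_species: str | None = None
    metadata: dict[str, str] = field(default_factory=dict)

    # -- construction helpers -------------------------------------------------
    def add_compartment(self, comp: Compartment) -> Compartment:
        if comp.id in self.compartments:
            raise ValueError(f"duplicate compartment id {comp.id!r}")
        self.compartments[comp.id] = comp
        return comp

    def add_species(self, sp: Species) -> Species:
        if sp.id in self.species:
            raise ValueError(f"duplicate species id {sp.id!r}")
        self.species[sp.id] = sp
        return sp

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        self.reactions[rxn.id] = rxn
        return rxn

    def copy(self) -> "NetworkModel":
        return copy.deepcopy(self)

    def sink_ids(self) -> set[str]:
        return {s.id for s in self.species.values() if s.role == "sink"}

    def initial_state(self) -> dict[str, float]:
        return {s.id: s.initial_concentration for s in self.species.values()}

    def fingerprint(self) -> str:
        """Order-insensitive content hash, used to verify purity of model surgery."""

        def law_key(law: KineticLaw):
            return (
                law.variant,
                law.k1,
                law.k2,
                law.Kcat,
                law.Km,
                law.enzyme,
                law.modifier,
                law.expression,
                sorted(law.parameters.items()),
            )

        doc = {
            "compartments": sorted(
                (c.id, c.name, c.volume) for c in self.compartments.values()
            ),
            "species": sorted(
                (
                    s.id,
                    s.name,
                    s.compartment,
                    s.role,
                    s.activation_state,
                    s.initial_concentration,
                    s.counterpart,
                    s.initial_overridden,
                )
                for s in self.species.values()
            ),
            "reactions": sorted(
                (
                    r.id,
                    sorted(map(tuple, r.substrates)),
                    sorted(map(tuple, r.products)),
                    sorted(r.modifiers),
                    law_key(r.law),
                    r.category,
                )
                for r in self.reactions.values()
            ),
            "output_species": self.output_species,
        }
        blob = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


# ---------------------------------------------------------------------------
# Rate-law arithmetic
# ---------------------------------------------------------------------------


def _check_nonneg(concs: Iterable[float], what: str) -> None:
    for c in concs:
        if c < 0:
            raise ValueError(f"negative {what} concentration: {c}")


def mass_action_rate(
    k1: float,
    k2: float | None,
    substrate_concs: Sequence[float],
    product_concs: Sequence[float] = (),
) -> float:
    """Net mass-action rate ``k1·∏S − k2·∏P`` (``k2`` absent → irreversible).

    An empty substrate list denotes constitutive synthesis (∏ over the empty
    set is 1, so the rate is simply ``k1``).
    """
    if k1 < 0 or (k2 is not None and k2 < 0):
        raise ValueError("rate constants must be non-negative")
    _check_nonneg(substrate_concs, "substrate")
    _check_nonneg(product_concs, "product")
    fwd = k1 * math.prod(substrate_concs)
    rev = (k2 or 0.0) * math.prod(product_concs)
    return fwd - rev


def hmm_rate(Kcat: float, enzyme_conc: float, Km: float, S: float) -> float:
    """Henri–Michaelis–Menten rate ``Kcat·E·S/(Km+S)``.

    Bounded above by ``Kcat·E`` and monotone non-decreasing in ``S``.  Pass
    ``enzyme_conc=1`` when the law has no enzyme species (``Kcat`` ≡ Vmax).
    """
    if Km <= 0:
        raise ValueError("Km must be strictly positive")
    if Kcat < 0:
        raise ValueError("Kcat must be non-negative")
    _check_nonneg((enzyme_conc, S), "input")
    return Kcat * enzyme_conc * S / (Km + S)


def modified_hmm_rate(Kcat: float, Km: float, modifier_conc: float, S: float) -> float:
    """Modifier-scaled HMM rate ``Kcat·M·S/(Km+S)``, linear in ``M``."""
    if Km <= 0:
        raise ValueError("Km must be strictly positive")
    if Kcat < 0:
        raise ValueError("Kcat must be non-negative")
    _check_nonneg((modifier_conc, S), "input")
    return Kcat * modifier_conc * S / (Km + S)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_network(model: NetworkModel) -> list[str]:
    """Check every structural invariant; return a list of violation messages.

    An empty list means the model is valid.  Validation reports and never
    raises: each message names the offending element and the broken rule.
    """
    v: list[str] = []
    if not model.compartments:
        v.append("model has no compartments (at least one is required)")
    for comp in model.compartments.values():
        if comp.volume <= 0:
            v.append(f"compartment {comp.id!r}: volume must be > 0, got {comp.volume}")

    sinks = model.sink_ids()
    for sp in model.species.values():
        if sp.compartment not in model.compartments:
            v.append(f"species {sp.id!r}: unknown compartment {sp.compartment!r}")
        if sp.role not in ROLES:
            v.append(f"species {sp.id!r}: unknown role {sp.role!r}")
        if sp.activation_state not in ACTIVATION_STATES:
            v.append(
                f"species {sp.id!r}: unknown activation state {sp.activation_state!r}"
            )
        if sp.initial_concentration < 0:
            v.append(
                f"species {sp.id!r}: initial concentration must be >= 0, "
                f"got {sp.initial_concentration}"
            )
        if sp.counterpart is not None and sp.counterpart not in model.species:
            v.append(f"species {sp.id!r}: unknown counterpart {sp.counterpart!r}")
        if (
            sp.activation_state == "active"
            and sp.counterpart is not None
            and sp.initial_concentration != 0
            and not sp.initial_overridden
        ):
            v.append(
                f"species {sp.id!r}: active state with a counterpart must start at "
                "zero concentration unless explicitly overridden by a scenario"
            )

    for rxn in model.reactions.values():
        for sid in rxn.participants():
            if sid not in model.species:
                v.append(f"reaction {rxn.id!r}: unknown species {sid!r}")
        for sid, stoich in rxn.substrates + rxn.products:
            if stoich <= 0:
                v.append(
                    f"reaction {rxn.id!r}: stoichiometry for {sid!r} must be a "
                    f"positive integer, got {stoich}"
                )
        if rxn.category not in CATEGORIES:
            v.append(f"reaction {rxn.id!r}: unknown category {rxn.category!r}")

        law = rxn.law
        if law.variant not in (MASS_ACTION, HMM, MODIFIED_HMM, OPAQUE):
            v.append(f"reaction {rxn.id!r}: unknown law variant {law.variant!r}")
        elif law.variant == MASS_ACTION:
            if law.k1 is None or law.k1 < 0:
                v.append(f"reaction {rxn.id!r}: mass-action k1 must be >= 0")
            if law.k2 is not None and law.k2 < 0:
                v.append(f"reaction {rxn.id!r}: mass-action k2 must be >= 0")
        elif law.variant in (HMM, MODIFIED_HMM):
            if law.Km is None or law.Km <= 0:
                v.append(f"reaction {rxn.id!r}: Km must be strictly positive")
            if law.Kcat is None or law.Kcat < 0:
                v.append(f"reaction {rxn.id!r}: Kcat must be >= 0")
            if not rxn.substrates:
                v.append(
                    f"reaction {rxn.id!r}: {law.variant} law requires a substrate"
                )
            if law.variant == MODIFIED_HMM:
                if law.modifier is None:
                    v.append(f"reaction {rxn.id!r}: ModifiedHMM law lacks a modifier")
                elif law.modifier not in rxn.modifiers:
                    v.append(
                        f"reaction {rxn.id!r}: ModifiedHMM modifier "
                        f"{law.modifier!r} is not in the reaction's modifier list"
                    )
        elif law.variant == OPAQUE and not law.expression:
            v.append(f"reaction {rxn.id!r}: opaque law has no expression")

        if rxn.category == "degradation":
            if len(rxn.substrates) != 1:
                v.append(
                    f"reaction {rxn.id!r}: degradation must have exactly one "
                    f"substrate, got {len(rxn.substrates)}"
                )
            bad = [p for p, _ in rxn.products if p not in sinks]
            if bad:
                v.append(
                    f"reaction {rxn.id!r}: degradation may only produce sink "
                    f"species, got {bad}"
                )
        if rxn.category == "transcription":
            if not any(
                model.species.get(p) is not None and model.species[p].role == "mRNA"
                for p, _ in rxn.products
            ):
                v.append(
                    f"reaction {rxn.id!r}: transcription must produce an "
                    "mRNA-role species"
                )
        if rxn.category == "translation":
            inputs = {s for s, _ in rxn.substrates} | set(rxn.modifiers)
            if law.enzyme:
                inputs.add(law.enzyme)
            if not any(
                model.species.get(s) is not None and model.species[s].role == "mRNA"
                for s in inputs
            ):
                v.append(
                    f"reaction {rxn.id!r}: translation must consume or be "
                    "modified by an mRNA-role species"
                )
            if not any(
                model.species.get(p) is not None and model.species[p].role == "protein"
                for p, _ in rxn.products
            ):
                v.append(
                    f"reaction {rxn.id!r}: translation must produce a "
                    "protein-role species"
                )

    # id-uniqueness across collections is enforced by the dict containers;
    # cross-collection collisions are harmless but reported for hygiene.
    if model.output_species is not None and model.output_species not in model.species:
        v.append(
            f"output species {model.output_species!r} is not a member of the model"
        )
    return v
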