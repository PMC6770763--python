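"""Model I/O: SBML import and the native YAML network format.

SBML Level 2/3 documents (including COPASI exports such as curated
BioModels deposits) are read into :class:`NetworkModel`.  Kinetic laws are
recognized structurally from the math tree after substituting parameter
values:

* ``k·∏[species]`` (optionally minus a reverse product) → mass action;
* ``V·S/(Km+S)`` → Henri–Michaelis–Menten, with an optional enzyme factor;
* ``Kcat·M·S/(Km+S)`` → the modifier-scaled HMM form.

A compartment-volume prefactor, which COPASI adds to amount-based rate
equations, is divided out before matching.  Anything unrecognized is kept
verbatim as an opaque symbolic rate and listed in the import report —
mapping never silently drops a law.  Events and non-rate rules have no
semantics in this engine and raise an explicit unsupported-feature error;
rate rules become pseudo-reactions with opaque laws.

The native format is a versioned YAML document that round-trips a
:class:`NetworkModel` losslessly (up to ordering).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import sympy
import yaml

from .network import (
    Compartment,
    KineticLaw,
    NetworkModel,
    Reaction,
    Species,
)

__all__ = [
    "ImportReport",
    "UnsupportedFeatureError",
    "SBMLParseError",
    "read_sbml",
    "read_native",
    "write_native",
    "NATIVE_SCHEMA",
]

NATIVE_SCHEMA = "pdl1net-network/1"


class SBMLParseError(ValueError):
    """Malformed SBML; message carries the reader's error log."""


class UnsupportedFeatureError(ValueError):
    """The document uses SBML constructs this engine cannot honor."""


@dataclass
class ImportReport:
    species_count: int = 0
    reaction_count: int = 0
    laws_by_variant: dict[str, int] = field(default_factory=dict)
    unmapped_laws: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def pretty(self) -> str:
        lines = [
            f"species: {self.species_count}",
            f"reactions: {self.reaction_count}",
            "laws mapped: "
            + ", ".join(f"{k}={v}" for k, v in sorted(self.laws_by_variant.items())),
        ]
        if self.unmapped_laws:
            lines.append("opaque (unmapped) laws: " + ", ".join(self.unmapped_laws))
        lines += [f"warning: {w}" for w in self.warnings]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# SBML import
# ---------------------------------------------------------------------------


def _role_from_sbml(species) -> str:
    name = (species.getName() or species.getId()).lower()
    if "mrna" in name:
        return "mRNA"
    if "gene" in name:
        return "gene"
    if "sink" in name or name in ("ø", "empty", "degraded"):
        return "sink"
    return "protein"


def _classify_law(
    expr: sympy.Expr,
    substrate_syms: list[sympy.Symbol],
    modifier_syms: list[sympy.Symbol],
    product_syms: list[sympy.Symbol],
) -> KineticLaw | None:
    """Structural pattern match of a (parameter-substituted) rate expression."""
    expr = sympy.simplify(expr)
    species_syms = set(substrate_syms) | set(modifier_syms) | set(product_syms)
    free = expr.free_symbols
    if free - species_syms:
        return None  # unresolved symbols: keep opaque

    # mass action: k1·∏S  or  k1·∏S − k2·∏P
    def _monomial_constant(e: sympy.Expr, syms: list[sympy.Symbol]):
        prod = sympy.Mul(*syms) if syms else sympy.Integer(1)
        k = sympy.simplify(e / prod) if syms else e
        return k if k.is_number and k >= 0 else None

    if substrate_syms:
        k1 = _monomial_constant(expr, substrate_syms)
        if k1 is not None:
            return KineticLaw.mass_action(float(k1))
        if product_syms:
            fwd_prod = sympy.Mul(*substrate_syms)
            rev_prod = sympy.Mul(*product_syms)
            diff = sympy.expand(expr)
            k1c = diff.coeff(fwd_prod)
            k2c = -diff.coeff(rev_prod)
            if (
                k1c.is_number
                and k2c.is_number
                and sympy.simplify(diff - (k1c * fwd_prod - k2c * rev_prod)) == 0
                and k1c >= 0
                and k2c >= 0
            ):
                return KineticLaw.mass_action(float(k1c), float(k2c))

        # HMM family: (prefactor)·S/(Km+S) with prefactor = Kcat[, ·E or ·M]
        S = substrate_syms[0]
        Km = sympy.Wild("Km", exclude=list(species_syms))
        A = sympy.Wild("A", exclude=[S])
        m = expr.match(A * S / (Km + S))
        if m and m[Km].is_number and m[Km] > 0:
            pre = sympy.simplify(m[A])
            km_val = float(m[Km])
            if pre.is_number and pre >= 0:
                return KineticLaw.hmm(float(pre), km_val)
            for sym in modifier_syms + substrate_syms + product_syms:
                ratio = sympy.simplify(pre / sym)
                if ratio.is_number and ratio >= 0:
                    if sym in modifier_syms:
                        return KineticLaw.modified_hmm(
                            float(ratio), km_val, str(sym)
                        )
                    return KineticLaw.hmm(float(ratio), km_val, enzyme=str(sym))
    return None


def read_sbml(source: str | Path) -> tuple[NetworkModel, ImportReport]:
    """Read an SBML document (path or XML string) into a NetworkModel.

    Amount-based species are converted to concentrations via their
    compartment size; boundary/constant species are flagged in metadata.
    Import is deterministic and preserves document order.
    """
    import libsbml

    reader = libsbml.SBMLReader()
    text = None
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("<")
    ):
        doc = reader.readSBML(str(source))
    else:
        text = source
        doc = reader.readSBMLFromString(text)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        log = [
            doc.getError(i).getMessage().strip()
            + f" (line {doc.getError(i).getLine()})"
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise SBMLParseError("malformed SBML:\n" + "\n".join(log))
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLParseError("document contains no model")

    if sbml_model.getNumEvents() > 0:
        raise UnsupportedFeatureError("SBML events are not supported")

    report = ImportReport()
    model = NetworkModel(
        metadata={
            "source": "sbml",
            "sbml_model_id": sbml_model.getId() or "",
            "sbml_level": str(doc.getLevel()),
        }
    )

    for i in range(sbml_model.getNumCompartments()):
        c = sbml_model.getCompartment(i)
        size = c.getSize()
        if not (size == size) or size <= 0:  # NaN or nonpositive -> nominal 1
            size = 1.0
            report.warnings.append(
                f"compartment {c.getId()!r} has no usable size; using 1.0"
            )
        model.add_compartment(
            Compartment(id=c.getId(), name=c.getName() or c.getId(), volume=size)
        )
    if not model.compartments:
        model.add_compartment(Compartment(id="default", volume=1.0))

    boundary = []
    for i in range(sbml_model.getNumSpecies()):
        s = sbml_model.getSpecies(i)
        comp = s.getCompartment() or next(iter(model.compartments))
        vol = model.compartments[comp].volume if comp in model.compartments else 1.0
        if s.isSetInitialConcentration():
            conc = s.getInitialConcentration()
        elif s.isSetInitialAmount():
            conc = s.getInitialAmount() / vol
        else:
            conc = 0.0
        if s.getBoundaryCondition() or s.getConstant():
            boundary.append(s.getId())
        model.add_species(
            Species(
                id=s.getId(),
                name=s.getName() or s.getId(),
                compartment=comp,
                role=_role_from_sbml(s),
                initial_concentration=max(conc, 0.0),
            )
        )
    if boundary:
        model.metadata["boundary_species"] = ",".join(boundary)

    # global + local parameters, by id
    global_params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }
    compartment_sizes = {cid: c.volume for cid, c in model.compartments.items()}

    for i in range(sbml_model.getNumRules()):
        rule = sbml_model.getRule(i)
        if not rule.isRate():
            raise UnsupportedFeatureError(
                "only rate rules are supported; found "
                f"{libsbml.SBMLTypeCode_toString(rule.getTypeCode(), 'core')}"
            )
        formula = libsbml.formulaToL3String(rule.getMath())
        rid = f"rate_rule_{rule.getVariable()}"
        model.add_reaction(
            Reaction(
                id=rid,
                products=[(rule.getVariable(), 1)],
                law=KineticLaw.opaque(formula, global_params),
                category="activation/inhibition",
                name=f"rate rule for {rule.getVariable()}",
            )
        )
        report.unmapped_laws.append(rid)

    for i in range(sbml_model.getNumReactions()):
        r = sbml_model.getReaction(i)
        substrates = [
            (r.getReactant(j).getSpecies(), int(r.getReactant(j).getStoichiometry() or 1))
            for j in range(r.getNumReactants())
        ]
        products = [
            (r.getProduct(j).getSpecies(), int(r.getProduct(j).getStoichiometry() or 1))
            for j in range(r.getNumProducts())
        ]
        modifiers = [
            r.getModifier(j).getSpecies() for j in range(r.getNumModifiers())
        ]

        kl = r.getKineticLaw()
        law = None
        formula = ""
        if kl is not None and kl.getMath() is not None:
            formula = libsbml.formulaToL3String(kl.getMath())
            local = {
                kl.getParameter(j).getId(): kl.getParameter(j).getValue()
                for j in range(kl.getNumParameters())
            }
            subs = {**global_params, **local}
            syms = {sid: sympy.Symbol(sid) for sid in model.species}
            locals_map = {
                **{k: sympy.Float(v) for k, v in subs.items()},
                **{k: sympy.Float(v) for k, v in compartment_sizes.items()},
                **syms,
            }
            try:
                expr = sympy.sympify(
                    formula.replace("^", "**"), locals=locals_map
                )
                comp_ids = set()
                for sid, _ in substrates + products:
                    comp_ids.add(model.species[sid].compartment)
                if len(comp_ids) == 1:
                    # COPASI multiplies amount rates by the compartment size
                    vol = compartment_sizes[comp_ids.pop()]
                    candidate = sympy.simplify(expr / vol)
                else:
                    candidate = expr
                for trial in (candidate, expr):
                    law = _classify_law(
                        trial,
                        [syms[s] for s, _ in substrates],
                        [syms[m] for m in modifiers],
                        [syms[p] for p, _ in products],
                    )
                    if law is not None:
                        break
            except (sympy.SympifyError, TypeError, KeyError):
                law = None
        if law is None:
            params = {}
            if kl is not None:
                params = {
                    **global_params,
                    **{
                        kl.getParameter(j).getId(): kl.getParameter(j).getValue()
                        for j in range(kl.getNumParameters())
                    },
                    **compartment_sizes,
                }
            law = KineticLaw.opaque(formula.replace("^", "**") or "0", params)
            report.unmapped_laws.append(r.getId())
        if law.variant == "ModifiedHMM" and law.modifier not in modifiers:
            modifiers.append(law.modifier)

        model.add_reaction(
            Reaction(
                id=r.getId(),
                name=r.getName() or r.getId(),
                substrates=substrates,
                products=products,
                modifiers=modifiers,
                law=law,
                category="degradation"
                if products
                and all(model.species[p].role == "sink" for p, _ in products)
                and len(substrates) == 1
                else "activation/inhibition",
            )
        )
        report.laws_by_variant[law.variant] = (
            report.laws_by_variant.get(law.variant, 0) + 1
        )

    report.species_count = len(model.species)
    report.reaction_count = sbml_model.getNumReactions()
    return model, report


# ---------------------------------------------------------------------------
# Native YAML format
# ---------------------------------------------------------------------------


def _law_to_doc(law: KineticLaw) -> dict:
    doc: dict = {"variant": law.variant}
    for name in ("k1", "k2", "Kcat", "Km", "enzyme", "modifier", "expression"):
        value = getattr(law, name)
        if value is not None:
            doc[name] = value
    if law.parameters:
        doc["parameters"] = dict(law.parameters)
    return doc


def _law_from_doc(doc: dict) -> KineticLaw:
    return KineticLaw(
        variant=doc["variant"],
        k1=doc.get("k1"),
        k2=doc.get("k2"),
        Kcat=doc.get("Kcat"),
        Km=doc.get("Km"),
        enzyme=doc.get("enzyme"),
        modifier=doc.get("modifier"),
        expression=doc.get("expression"),
        parameters=dict(doc.get("parameters", {})),
    )


def write_native(model: NetworkModel, path: str | Path) -> None:
    """Serialize the model to the versioned YAML network format."""
    doc = {
        "schema": NATIVE_SCHEMA,
        "metadata": dict(model.metadata),
        "output_species": model.output_species,
        "compartments": [
            {"id": c.id, "name": c.name, "volume": c.volume}
            for c in model.compartments.values()
        ],
        "species": [
            {
                "id": s.id,
                "name": s.name,
                "compartment": s.compartment,
                "role": s.role,
                "activation_state": s.activation_state,
                "initial_concentration": s.initial_concentration,
                "counterpart": s.counterpart,
                "initial_overridden": s.initial_overridden,
            }
            for s in model.species.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "category": r.category,
                "substrates": [[sid, st] for sid, st in r.substrates],
                "products": [[sid, st] for sid, st in r.products],
                "modifiers": list(r.modifiers),
                "law": _law_to_doc(r.law),
                "citations": list(r.citations),
            }
            for r in model.reactions.values()
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_native(path: str | Path) -> NetworkModel:
    """Load a model from the native YAML format; write∘read is the identity."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or doc.get("schema") != NATIVE_SCHEMA:
        raise ValueError(
            f"unrecognized schema {doc.get('schema') if isinstance(doc, dict) else doc!r}; "
            f"expected {NATIVE_SCHEMA!r}"
        )
    model = NetworkModel(
        output_species=doc.get("output_species"),
        metadata=dict(doc.get("metadata", {})),
    )
    for c in doc.get("compartments", []):
        model.add_compartment(Compartment(**c))
    for s in doc.get("species", []):
        model.add_species(Species(**s))
    for r in doc.get("reactions", []):
        model.add_reaction(
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                category=r.get("category", "activation/inhibition"),
                substrates=[(sid, st) for sid, st in r.get("substrates", [])],
                products=[(sid, st) for sid, st in r.get("products", [])],
                modifiers=list(r.get("modifiers", [])),
                law=_law_from_doc(r["law"]),
                citations=list(r.get("citations", [])),
            )
        )
    return model
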