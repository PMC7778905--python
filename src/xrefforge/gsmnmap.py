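"""SBML model reading, namespace mapping and diagnostics.

Models are read from SBML Level 2 or Level 3 (with or without the FBC
package) into a light stoichiometric container.  Mapping a model onto the
unified namespace resolves each species by, in order of precedence,
(1) a namespace-qualified annotation, (2) its declared id interpreted as a
source cross-reference, (3) an exact normalized-name match; species that
resolve nowhere keep their model-local ids.  Reactions are then rewritten
within the model's own compartments; equations whose sides cancel entirely
are dropped (with a diagnostic), and reactions whose canonical keys collide
are reported as merged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from fractions import Fraction

import libsbml

from .reacspace import (
    Direction,
    Equation,
    Term,
    canonical_key,
    normalize_equation,
    rewrite_equation,
)
from .reconcile import NamespaceEntry, normalize_name

logger = logging.getLogger(__name__)

__all__ = [
    "Species",
    "ModelReaction",
    "Model",
    "SpeciesOutcome",
    "ReactionOutcome",
    "MappingReport",
    "read_model",
    "write_model",
    "map_model",
    "write_report",
]

DEFAULT_BIG_M = 1000.0


@dataclass
class Species:
    id: str
    name: str
    compartment: str
    boundary: bool = False
    annotations: tuple[tuple[str, str], ...] = ()


@dataclass
class ModelReaction:
    id: str
    name: str
    equation: Equation
    lower: float
    upper: float


@dataclass
class Model:
    model_id: str
    compartments: list[str]
    species: list[Species]
    reactions: list[ModelReaction]
    objective: str | None = None


class SpeciesOutcome(Enum):
    MAPPED_BY_ANNOTATION = "MAPPED_BY_ANNOTATION"
    MAPPED_BY_ID = "MAPPED_BY_ID"
    MAPPED_BY_NAME = "MAPPED_BY_NAME"
    UNMAPPED = "UNMAPPED"


class ReactionOutcome(Enum):
    ONE_TO_ONE = "ONE_TO_ONE"
    MERGED = "MERGED"
    EMPTIED = "EMPTIED"
    UNMAPPED_PARTICIPANT = "UNMAPPED_PARTICIPANT"


@dataclass
class MappingReport:
    species_outcomes: dict[str, SpeciesOutcome] = field(default_factory=dict)
    reaction_outcomes: dict[str, ReactionOutcome] = field(default_factory=dict)
    messages: list[tuple[str, str, str]] = field(default_factory=list)  # severity, entity, text
    reaction_map: dict[str, str] = field(default_factory=dict)  # model rxn id -> mapped rxn id

    def log(self, severity: str, entity: str, text: str) -> None:
        self.messages.append((severity, entity, text))


_IDENTIFIERS_URI = re.compile(r"identifiers\.org/([^/:]+)[/:](.+)$")


def _parse_annotation_uri(uri: str) -> tuple[str, str] | None:
    m = _IDENTIFIERS_URI.search(uri)
    if not m:
        return None
    prefix, local = m.group(1), m.group(2)
    if ":" in local:  # e.g. CHEBI:15377 under the chebi collection
        local = local.rsplit(":", 1)[1]
    return prefix, local


def _species_annotations(sp) -> tuple[tuple[str, str], ...]:
    out = []
    for i in range(sp.getNumCVTerms()):
        term = sp.getCVTerm(i)
        for j in range(term.getNumResources()):
            parsed = _parse_annotation_uri(term.getResourceURI(j))
            if parsed:
                out.append(parsed)
    return tuple(out)


def _reaction_bounds(model, rxn, fbc_rxn, big_m: float) -> tuple[float, float]:
    if fbc_rxn is not None and fbc_rxn.isSetLowerFluxBound():
        lo = model.getParameter(fbc_rxn.getLowerFluxBound()).getValue()
        hi = model.getParameter(fbc_rxn.getUpperFluxBound()).getValue()
        return lo, hi
    kl = rxn.getKineticLaw()
    if kl is not None:
        lo_p = kl.getParameter("LOWER_BOUND")
        hi_p = kl.getParameter("UPPER_BOUND")
        if lo_p is not None and hi_p is not None:
            return lo_p.getValue(), hi_p.getValue()
    if rxn.isSetReversible() and not rxn.getReversible():
        return 0.0, big_m
    return -big_m, big_m


def read_model(path: str, big_m: float = DEFAULT_BIG_M) -> Model:
    """Read an SBML L2/L3 (+FBC) file into a Model.

    Missing bounds default to [0, big_m] for irreversible reactions and
    [-big_m, big_m] for reversible ones; infinite bounds are clamped to
    +-big_m.  Boundary species are taken from the ``boundaryCondition``
    flag or membership in a compartment named "boundary" or "b".
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage().strip()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise ValueError(f"invalid SBML in {path}: " + " | ".join(msgs))
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ValueError(f"no model element in {path}")

    compartments = [c.getId() for c in sbml_model.getListOfCompartments()]
    boundary_compartments = {c for c in compartments if c.lower() in ("boundary", "b")}

    species = []
    for sp in sbml_model.getListOfSpecies():
        species.append(Species(
            id=sp.getId(),
            name=sp.getName() or sp.getId(),
            compartment=sp.getCompartment(),
            boundary=sp.getBoundaryCondition() or sp.getCompartment() in boundary_compartments,
            annotations=_species_annotations(sp),
        ))
    comp_of = {s.id: s.compartment for s in species}

    fbc = sbml_model.getPlugin("fbc")
    reactions = []
    for rxn in sbml_model.getListOfReactions():
        fbc_rxn = rxn.getPlugin("fbc")
        lo, hi = _reaction_bounds(sbml_model, rxn, fbc_rxn, big_m)
        lo = max(lo, -big_m) if lo != float("-inf") else -big_m
        hi = min(hi, big_m) if hi != float("inf") else big_m

        def side(refs):
            return tuple(
                Term(
                    ref.getSpecies(),
                    Fraction(ref.getStoichiometry() if ref.isSetStoichiometry() else 1).limit_denominator(10**6),
                    comp_of.get(ref.getSpecies()),
                )
                for ref in refs
            )

        direction = Direction.BIDIRECTIONAL if (not rxn.isSetReversible() or rxn.getReversible()) else Direction.LR
        reactions.append(ModelReaction(
            id=rxn.getId(),
            name=rxn.getName() or rxn.getId(),
            equation=Equation(side(rxn.getListOfReactants()), side(rxn.getListOfProducts()), direction),
            lower=lo,
            upper=hi,
        ))

    objective = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        active = fbc.getActiveObjective() or fbc.getObjective(0)
        if active is not None and active.getNumFluxObjectives() > 0:
            objective = active.getFluxObjective(0).getReaction()

    return Model(
        model_id=sbml_model.getId() or "model",
        compartments=compartments,
        species=species,
        reactions=reactions,
        objective=objective,
    )


def write_model(model: Model, path: str) -> None:
    """Write a Model as SBML Level 3 Version 1 with FBC v2 bounds."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.model_id)
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    for cid in model.compartments:
        comp = sbml_model.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)

    for s in model.species:
        sp = sbml_model.createSpecies()
        sp.setId(s.id)
        sp.setName(s.name)
        sp.setCompartment(s.compartment)
        sp.setBoundaryCondition(s.boundary)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for r in model.reactions:
        rxn = sbml_model.createReaction()
        rxn.setId(r.id)
        rxn.setName(r.name)
        rxn.setReversible(r.lower < 0)
        rxn.setFast(False)
        for t in r.equation.left:
            ref = rxn.createReactant()
            ref.setSpecies(t.met)
            ref.setStoichiometry(float(t.coeff))
            ref.setConstant(True)
        for t in r.equation.right:
            ref = rxn.createProduct()
            ref.setSpecies(t.met)
            ref.setStoichiometry(float(t.coeff))
            ref.setConstant(True)
        rplug = rxn.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(r.lower))
        rplug.setUpperFluxBound(bound_param(r.upper))

    if model.objective:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(model.objective)
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


def _species_lookup(entries: list[NamespaceEntry]):
    by_xref: dict[tuple[str, str], str] = {}
    by_name: dict[str, str] = {}
    ambiguous_names: set[str] = set()
    mnx_ids: set[str] = set()
    for e in entries:
        mnx_ids.add(e.mnx_id)
        for ref in e.members:
            by_xref[ref] = e.mnx_id
        key = normalize_name(e.name)
        if key in by_name and by_name[key] != e.mnx_id:
            ambiguous_names.add(key)
        else:
            by_name[key] = e.mnx_id
    for key in ambiguous_names:
        del by_name[key]
    return by_xref, by_name, mnx_ids


def _id_candidates(species_id: str) -> list[tuple[str, str]]:
    cands = []
    sid = species_id[2:] if species_id.startswith("M_") else species_id
    for sep in (":", "_"):
        if sep in sid:
            prefix, local = sid.split(sep, 1)
            cands.append((prefix, local))
    return cands


def map_model(
    model: Model,
    entries: list[NamespaceEntry],
) -> tuple[Model, MappingReport]:
    """Map a model onto the namespace; returns the mapped model and report.

    The mapped model has one species per (namespace id, compartment),
    reactions rewritten with cancellation (empty ones dropped), and one
    reaction per canonical key (key collisions are merges).  Stoichiometry
    of untouched reactions is preserved exactly.
    """
    by_xref, by_name, mnx_ids = _species_lookup(entries)
    report = MappingReport()

    mapping: dict[str, str] = {}
    for s in model.species:
        target: str | None = None
        outcome = SpeciesOutcome.UNMAPPED
        for ann in s.annotations:
            if ann in by_xref:
                target, outcome = by_xref[ann], SpeciesOutcome.MAPPED_BY_ANNOTATION
                break
        if target is None:
            if s.id in mnx_ids:
                target, outcome = s.id, SpeciesOutcome.MAPPED_BY_ID
            else:
                for cand in _id_candidates(s.id):
                    if cand in by_xref:
                        target, outcome = by_xref[cand], SpeciesOutcome.MAPPED_BY_ID
                        break
        if target is None:
            hit = by_name.get(normalize_name(s.name))
            if hit is not None:
                target, outcome = hit, SpeciesOutcome.MAPPED_BY_NAME
        elif outcome is SpeciesOutcome.MAPPED_BY_ANNOTATION:
            name_hit = by_name.get(normalize_name(s.name))
            if name_hit is not None and name_hit != target:
                report.log(
                    "WARNING", s.id,
                    f"annotation maps to {target} but name matches {name_hit}; annotation wins",
                )
        report.species_outcomes[s.id] = outcome
        mapping[s.id] = target if target is not None else s.id
        if outcome is SpeciesOutcome.UNMAPPED:
            report.log("INFO", s.id, "species not found in namespace; keeping model-local id")

    unmapped_species = {
        sid for sid, o in report.species_outcomes.items() if o is SpeciesOutcome.UNMAPPED
    }

    rewritten: list[tuple[ModelReaction, Equation, str, bool]] = []
    for rxn in model.reactions:
        participants = {t.met for t in (*rxn.equation.left, *rxn.equation.right)}
        eq = rewrite_equation(rxn.equation, mapping)
        if eq.is_empty:
            report.reaction_outcomes[rxn.id] = ReactionOutcome.EMPTIED
            report.log(
                "WARNING", rxn.id,
                "equation cancels entirely after mapping; reaction will disappear from the mapped GSMN",
            )
            continue
        if participants & unmapped_species:
            report.reaction_outcomes[rxn.id] = ReactionOutcome.UNMAPPED_PARTICIPANT
            report.log("INFO", rxn.id, "reaction kept with unmapped participant(s)")
        key, flipped = canonical_key(eq)
        rewritten.append((rxn, eq, key, flipped))

    by_key: dict[str, list[tuple[ModelReaction, Equation, bool]]] = {}
    for rxn, eq, key, flipped in rewritten:
        by_key.setdefault(key, []).append((rxn, eq, flipped))

    mapped_species: dict[tuple[str, str | None], Species] = {}
    comp_name = {s.id: s for s in model.species}
    for s in model.species:
        key = (mapping[s.id], s.compartment)
        if key not in mapped_species:
            mapped_species[key] = Species(
                id=f"{mapping[s.id]}__{s.compartment}" if mapping[s.id] != s.id else s.id,
                name=s.name,
                compartment=s.compartment,
                boundary=s.boundary,
                annotations=s.annotations,
            )
        elif s.boundary:
            mapped_species[key].boundary = True

    species_id_of = {
        (mnx, comp): sp.id for (mnx, comp), sp in mapped_species.items()
    }

    mapped_reactions: list[ModelReaction] = []
    for key, group in by_key.items():
        main_rxn, main_eq, main_flip = group[0]
        if len(group) > 1:
            for rxn, _, _ in group:
                report.reaction_outcomes[rxn.id] = ReactionOutcome.MERGED
                others = ", ".join(r.id for r, _, _ in group if r.id != rxn.id)
                report.log("WARNING", rxn.id, f"canonical key collides with {others}; reactions merged")
        else:
            report.reaction_outcomes.setdefault(main_rxn.id, ReactionOutcome.ONE_TO_ONE)

        def remap_side(side):
            return tuple(
                replace(t, met=species_id_of.get((t.met, t.compartment), t.met))
                for t in side
            )

        # bounds of members written in the opposite orientation (e.g. an
        # import merged with the matching export) are mirrored before
        # combination, so merging never loses flux capability
        lowers, uppers = [], []
        for r, _, flip in group:
            if flip != main_flip:
                lowers.append(-r.upper)
                uppers.append(-r.lower)
            else:
                lowers.append(r.lower)
                uppers.append(r.upper)
        lower = min(lowers)
        upper = max(uppers)
        mapped_reactions.append(ModelReaction(
            id=main_rxn.id,
            name=main_rxn.name,
            equation=Equation(remap_side(main_eq.left), remap_side(main_eq.right), main_eq.direction),
            lower=lower,
            upper=upper,
        ))
        for rxn, _, _ in group:
            report.reaction_map[rxn.id] = main_rxn.id

    mapped = Model(
        model_id=model.model_id + "_mapped",
        compartments=model.compartments,
        species=list(mapped_species.values()),
        reactions=mapped_reactions,
        objective=model.objective if model.objective in {r.id for r in mapped_reactions} else None,
    )
    return mapped, report


def write_report(report: MappingReport, path: str) -> None:
    """Write the mapping report as a TSV of (entity, kind, outcome/severity, message)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#entity\tkind\toutcome\tmessage\n")
        for sid, outcome in sorted(report.species_outcomes.items()):
            fh.write(f"{sid}\tspecies\t{outcome.value}\t\n")
        for rid, r_outcome in sorted(report.reaction_outcomes.items()):
            fh.write(f"{rid}\treaction\t{r_outcome.value}\t\n")
        for severity, entity, text in report.messages:
            fh.write(f"{entity}\tmessage\t{severity}\t{text}\n")
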