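"""Synthetic source databases and models with known ground truth.

The generator emulates the statistical situation the reconciliation faces:
several overlapping source namespaces describing the same compounds, where
a copy of a compound may carry a protonation-shifted InChI, an InChI with
the stereo layers erased, or no structure at all (name and formula only);
shared reactions are written per-source and cross-referenced.  Synthetic
InChIs come from a small valid grammar (carbon-skeleton formulas, chain
connectivity, optional stereo and protonation layers) rather than real
chemistry, so the structure machinery is exercised without a
cheminformatics dependency.

Status-model generation assembles disjoint stoichiometric motifs with
provable flux status (open chains: A; wrong-way exchanges: a; internal
loops needing a reversal: b; dead ends: B), joined through a hub metabolite
that appears catalytically (net zero) so connectivity never changes any
status.  Motif sizes make no classification tolerance-marginal.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np

from .gsmnmap import Model, ModelReaction, Species
from .reacspace import Direction, Equation, Term
from .reconcile import MergePartition, MetRef, SourceMetabolite, SourceReaction
from .fluxstatus import Status

__all__ = [
    "FixtureConfig",
    "GroundTruth",
    "DEFAULT_CONFIG",
    "FIGURE1_CONFIG",
    "STATUS_MIX_BLOCKS",
    "generate_sources",
    "generate_model",
    "figure1_sources",
    "merge_metrics",
    "write_fixture_dir",
]


@dataclass(frozen=True)
class FixtureConfig:
    n_true_compounds: int = 40
    n_sources: int = 3
    structure_dropout: float = 0.25
    protonation_perturb: float = 0.5
    stereo_erase: float = 0.25
    n_shared_reactions: int = 40
    xref_density: float = 1.0
    n_acid_base: int = 3
    model_blocks: dict = field(default_factory=lambda: dict(STATUS_MIX_BLOCKS))
    seed: int = 42

    def __post_init__(self) -> None:
        for p in (self.structure_dropout, self.protonation_perturb, self.stereo_erase, self.xref_density):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")


STATUS_MIX_BLOCKS = {Status.A: 6, Status.a: 4, Status.b: 3, Status.B: 3}

DEFAULT_CONFIG = FixtureConfig()


@dataclass
class GroundTruth:
    # compound index -> refs of all its copies
    true_partition: dict[int, list[MetRef]] = field(default_factory=dict)
    planted_conflicts: list[tuple[str, str]] = field(default_factory=list)
    true_statuses: dict[str, Status] = field(default_factory=dict)
    expected_nonempty_reactions: int | None = None

    def true_pairs(self) -> set[frozenset[MetRef]]:
        pairs: set[frozenset[MetRef]] = set()
        for refs in self.true_partition.values():
            for i, a in enumerate(refs):
                for b in refs[i + 1:]:
                    if a != b:
                        pairs.add(frozenset((a, b)))
        return pairs


# --------------------------------------------------------------------------
# synthetic chemistry
# --------------------------------------------------------------------------

def _compound_inchi(i: int, with_stereo: bool) -> tuple[str, str, int]:
    """Synthetic standard-InChI, Hill formula and charge for compound i.

    Heavy-atom composition is unique per index, connectivity is a simple
    chain, hydrogens saturate the chain; every second stereo-eligible
    compound carries /t /m /s layers.
    """
    n_c = 2 + i // 4
    n_o = 1 + i % 2
    n_n = i % 4 // 2
    heavy = n_c + n_o + n_n
    n_h = 2 * n_c + 2 + n_n  # saturated chain with amine hydrogens

    def tok(el: str, n: int) -> str:
        return "" if n == 0 else el if n == 1 else f"{el}{n}"

    formula = tok("C", n_c) + tok("H", n_h) + tok("N", n_n) + tok("O", n_o)
    conn = "-".join(str(k) for k in range(1, heavy + 1))
    h_layer = f"1-{n_c}H2" if n_c > 1 else "1H2"
    inchi = f"InChI=1S/{formula}/c{conn}/h{h_layer}"
    if with_stereo:
        inchi += "/t2-/m0/s1"
    return inchi, formula, 0


def _perturb_protonation(inchi: str, charge: int, delta: int) -> tuple[str, int]:
    # standard InChI keeps the neutral-form formula and notes proton
    # addition/removal in the /p layer
    return f"{inchi}/p{delta:+d}" if "/p" not in inchi else inchi, charge + delta


def _erase_stereo(inchi: str) -> str:
    return inchi.split("/t")[0] if "/t" in inchi else inchi


def _names(i: int) -> tuple[str, ...]:
    return (f"compound-{i:04d}", f"cpd {i}")


# --------------------------------------------------------------------------
# source corpus generation
# --------------------------------------------------------------------------

def generate_sources(
    config: FixtureConfig = DEFAULT_CONFIG,
) -> tuple[list[SourceMetabolite], list[SourceReaction], GroundTruth]:
    """Generate a cross-referenced multi-source corpus with ground truth.

    Every source carries a copy of every compound; copies are independently
    perturbed (structure dropout, protonation shift, stereo erasure).
    Shared reactions are emitted once per source over that source's local
    ids, cross-referenced across sources at ``xref_density`` (each copy
    links to every other source's copy independently).  Acid/base conflict
    reactions are planted in the first source over dedicated compounds.
    """
    if config.n_shared_reactions > 0 and config.n_true_compounds < 4:
        raise ValueError("need at least 4 compounds to build shared reactions")
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    metabolites: list[SourceMetabolite] = []
    reactions: list[SourceReaction] = []

    has_stereo = {i: i % 2 == 0 for i in range(config.n_true_compounds)}
    prefixes = [f"S{s}" for s in range(config.n_sources)]

    local_of: dict[tuple[int, int], str] = {}  # (source, compound) -> local id
    for s, prefix in enumerate(prefixes):
        for i in range(config.n_true_compounds):
            base_inchi, formula, charge = _compound_inchi(i, has_stereo[i])
            inchi: str | None = base_inchi
            if rng.random() < config.structure_dropout:
                inchi = None
            else:
                if has_stereo[i] and rng.random() < config.stereo_erase:
                    inchi = _erase_stereo(inchi)
                if rng.random() < config.protonation_perturb:
                    delta = int(rng.choice([-1, 1]))
                    inchi, charge = _perturb_protonation(inchi, charge, delta)
            local_id = f"M{i:04d}"
            local_of[(s, i)] = local_id
            metabolites.append(SourceMetabolite(
                prefix=prefix, local_id=local_id, names=_names(i),
                formula=formula, charge=charge, inchi=inchi,
            ))
            truth.true_partition.setdefault(i, []).append((prefix, local_id))

    # shared reactions: a sliding window over a compound permutation, so
    # every compound takes part in several reactions — enough context that a
    # perturbed copy is usually the *single* unmatched term in some
    # cross-referenced reaction pair
    participants: list[tuple[list[int], list[int]]] = []
    order = list(rng.permutation(config.n_true_compounds))
    for j in range(config.n_shared_reactions):
        picks = [order[(j + k) % config.n_true_compounds] for k in range(4)]
        if len(set(picks)) < 4:
            picks = list(rng.choice(config.n_true_compounds, size=4, replace=False))
        participants.append((picks[:2], picks[2:]))

    for j, (lhs, rhs) in enumerate(participants):
        for s, prefix in enumerate(prefixes):
            xrefs = []
            for s2, prefix2 in enumerate(prefixes):
                if s2 != s and rng.random() < config.xref_density:
                    xrefs.append((prefix2, f"R{j:04d}"))
            eq = Equation(
                tuple(Term(local_of[(s, i)], Fraction(1)) for i in lhs),
                tuple(Term(local_of[(s, i)], Fraction(1)) for i in rhs),
                Direction.LR,
            )
            reactions.append(SourceReaction(
                prefix=prefix, local_id=f"R{j:04d}", equation=eq,
                direction=Direction.LR, xrefs=tuple(xrefs),
            ))

    # planted acid/base conflicts: two protonation variants of a dedicated
    # compound on the two sides of one reaction in the first source
    for k in range(config.n_acid_base):
        i = config.n_true_compounds + k
        inchi, formula, charge = _compound_inchi(i, with_stereo=False)
        acid_id, base_id = f"MA{k:02d}", f"MB{k:02d}"
        inchi_base, charge_base = _perturb_protonation(inchi, charge, -1)
        metabolites.append(SourceMetabolite(
            prefix=prefixes[0], local_id=acid_id, names=(f"acid-{k}",),
            formula=formula, charge=charge, inchi=inchi,
        ))
        metabolites.append(SourceMetabolite(
            prefix=prefixes[0], local_id=base_id, names=(f"base-{k}",),
            formula=formula, charge=charge_base, inchi=inchi_base,
        ))
        truth.true_partition[i] = [(prefixes[0], acid_id), (prefixes[0], base_id)]
        rxn_id = f"RC{k:02d}"
        reactions.append(SourceReaction(
            prefix=prefixes[0], local_id=rxn_id,
            equation=Equation(
                (Term(acid_id, Fraction(1)),), (Term(base_id, Fraction(1)),),
                Direction.LR,
            ),
            direction=Direction.LR,
        ))
        truth.planted_conflicts.append((prefixes[0], rxn_id))

    return metabolites, reactions, truth


def figure1_sources() -> tuple[list[SourceMetabolite], list[SourceReaction], GroundTruth]:
    """The worked progressive-reconciliation example: five source
    metabolites in four cross-referenced reactions collapse to two
    namespace metabolites in a single reaction, one evidence pass at a time.

    Compound X has three copies — two byte-identical InChIs (pass 1), one
    stereo-erased (pass 2); compound Y has a structured copy and a
    name-only copy (pass 3).
    """
    x_inchi, x_formula, _ = _compound_inchi(0, with_stereo=True)
    y_inchi, y_formula, _ = _compound_inchi(1, with_stereo=False)
    mets = [
        SourceMetabolite("S0", "A0", ("L-widgetine",), x_formula, 0, x_inchi),
        SourceMetabolite("S0", "B0", ("gadgetol",), y_formula, 0, y_inchi),
        SourceMetabolite("S1", "A1", ("L-widgetine",), x_formula, 0, x_inchi),
        SourceMetabolite("S1", "A2", ("widgetine",), x_formula, 0, _erase_stereo(x_inchi)),
        SourceMetabolite("S1", "B1", ("Gadgetol",), y_formula, 0, None),
    ]
    one = Fraction(1)
    rxns = [
        SourceReaction("S0", "r0",
                       Equation((Term("A0", one),), (Term("B0", one),), Direction.LR),
                       Direction.LR),
        SourceReaction("S0", "r3",
                       Equation((Term("B0", one),), (Term("A0", one),), Direction.LR),
                       Direction.LR),
        SourceReaction("S1", "r1",
                       Equation((Term("A1", one),), (Term("B1", one),), Direction.LR),
                       Direction.LR, xrefs=(("S0", "r0"),)),
        SourceReaction("S1", "r2",
                       Equation((Term("A2", one),), (Term("B1", one),), Direction.LR),
                       Direction.LR, xrefs=(("S0", "r0"),)),
    ]
    truth = GroundTruth(
        true_partition={
            0: [("S0", "A0"), ("S1", "A1"), ("S1", "A2")],
            1: [("S0", "B0"), ("S1", "B1")],
        },
        expected_nonempty_reactions=1,
    )
    return mets, rxns, truth


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def merge_metrics(partition: MergePartition, truth: GroundTruth) -> tuple[float, float]:
    """(precision, recall) of merged pairs against the ground truth."""
    got = partition.merged_pairs()
    want = truth.true_pairs()
    if not got:
        return 1.0, 0.0 if want else 1.0
    tp = len(got & want)
    precision = tp / len(got)
    recall = tp / len(want) if want else 1.0
    return precision, recall


# --------------------------------------------------------------------------
# status-model generation
# --------------------------------------------------------------------------

def _decompose(count: int, label: str) -> list[int]:
    """Split a block count into motif sizes from {2, 3}."""
    if count == 0:
        return []
    if count == 1:
        raise ValueError(f"cannot build a {label} block of size 1: the smallest "
                         f"provable {label} motif has 2 reactions")
    sizes = []
    while count > 3:
        sizes.append(2)
        count -= 2
    sizes.append(count)
    return sizes


def generate_model(
    blocks: dict[Status, int] | None = None,
    big_m: float = 1000.0,
    hub: bool = True,
) -> tuple[Model, GroundTruth]:
    """Assemble a model from status motifs with provable classification.

    Blocks: A — hub import/export (+ extra exports or an internal cycle
    through the hub); a — import-only pockets that drain once an exchange
    may reverse; b — parallel or triangle internal loops needing one
    reversal; B — closed dead-end reactions.  The hub metabolite is added
    catalytically (equal stoichiometry on both sides) to one reaction per
    non-A motif, connecting the network without altering any mass balance.
    """
    blocks = dict(STATUS_MIX_BLOCKS) if blocks is None else blocks
    blocks = {s: blocks.get(s, 0) for s in Status}
    if all(v == 0 for v in blocks.values()):
        return Model("empty", ["c"], [], []), GroundTruth()
    if 0 < blocks[Status.A] < 2:
        raise ValueError("an A block needs at least 2 reactions (hub import + export)")

    one = Fraction(1)
    species: dict[str, Species] = {}
    reactions: list[ModelReaction] = []
    truth = GroundTruth()

    def sp(sid: str) -> str:
        if sid not in species:
            species[sid] = Species(id=sid, name=sid, compartment="c")
        return sid

    def rxn(rid: str, left, right, lower, upper, status: Status) -> None:
        reactions.append(ModelReaction(
            rid, rid,
            Equation(
                tuple(Term(sp(m), Fraction(c), "c") for m, c in left),
                tuple(Term(sp(m), Fraction(c), "c") for m, c in right),
                Direction.BIDIRECTIONAL if lower < 0 else Direction.LR,
            ),
            lower, upper,
        ))
        truth.true_statuses[rid] = status

    hub_met = "HUB"
    use_hub = hub and blocks[Status.A] >= 2
    catalytic = ([(hub_met, 1)], [(hub_met, 1)]) if use_hub else ([], [])

    if blocks[Status.A]:
        rxn("EX_hub_in", [], [(hub_met, 1)], 0, big_m, Status.A)
        rxn("EX_hub_out", [(hub_met, 1)], [], 0, big_m, Status.A)
        extra = blocks[Status.A] - 2
        if extra == 1:
            rxn("EX_hub_out2", [(hub_met, 1)], [], 0, big_m, Status.A)
        elif extra >= 2:
            chain = [hub_met] + [f"AC{i}" for i in range(extra - 1)] + [hub_met]
            for i in range(extra):
                rxn(f"R_acyc{i}", [(chain[i], 1)], [(chain[i + 1], 1)], 0, big_m, Status.A)

    # the catalytic hub term may only be attached to *internal* reactions:
    # a non-empty side with a non-boundary species would stop an exchange
    # from being recognized as a boundary reaction
    for bi, size in enumerate(_decompose(blocks[Status.a], "a")):
        cl, cr = catalytic
        if size == 2:
            met = f"aP{bi}"
            rxn(f"EX_a{bi}_1", [], [(met, 1)], 0, big_m, Status.a)
            rxn(f"EX_a{bi}_2", [], [(met, 1)], 0, big_m, Status.a)
        else:
            m1, m2 = f"aP{bi}x", f"aP{bi}y"
            rxn(f"EX_a{bi}_1", [], [(m1, 1)], 0, big_m, Status.a)
            rxn(f"R_a{bi}", cl + [(m1, 1)], cr + [(m2, 1)], 0, big_m, Status.a)
            rxn(f"EX_a{bi}_2", [], [(m2, 1)], 0, big_m, Status.a)

    for bi, size in enumerate(_decompose(blocks[Status.b], "b")):
        cl, cr = catalytic
        if size == 2:
            m1, m2 = f"bQ{bi}x", f"bQ{bi}y"
            rxn(f"R_b{bi}_1", cl + [(m1, 1)], cr + [(m2, 1)], 0, big_m, Status.b)
            rxn(f"R_b{bi}_2", [(m1, 1)], [(m2, 1)], 0, big_m, Status.b)
        else:
            m1, m2, m3 = f"bQ{bi}x", f"bQ{bi}y", f"bQ{bi}z"
            rxn(f"R_b{bi}_1", cl + [(m1, 1)], cr + [(m2, 1)], 0, big_m, Status.b)
            rxn(f"R_b{bi}_2", [(m2, 1)], [(m3, 1)], 0, big_m, Status.b)
            rxn(f"R_b{bi}_3", [(m1, 1)], [(m3, 1)], 0, big_m, Status.b)

    for k in range(blocks[Status.B]):
        cl, cr = catalytic
        rxn(f"R_dead{k}", cl + [(f"D{k}x", 1)], cr + [(f"D{k}y", 1)], 0, big_m, Status.B)

    model = Model(
        model_id="status_fixture",
        compartments=["c"],
        species=list(species.values()),
        reactions=reactions,
    )
    return model, truth


# --------------------------------------------------------------------------
# on-disk presets
# --------------------------------------------------------------------------

def write_fixture_dir(preset: str, seed: int, out_dir: str | Path) -> GroundTruth:
    """Materialize a preset (sources + SBML model + ground truth JSON)."""
    from . import nsio
    from .gsmnmap import write_model

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if preset == "figure1":
        mets, rxns, truth = figure1_sources()
    elif preset == "default":
        mets, rxns, truth = generate_sources(dataclasses.replace(DEFAULT_CONFIG, seed=seed))
    elif preset == "status-mix":
        mets, rxns, truth = generate_sources(dataclasses.replace(DEFAULT_CONFIG, seed=seed))
    else:
        raise ValueError(f"unknown preset {preset!r}")
    nsio.write_sources(mets, rxns, out_dir / "sources")

    model, model_truth = generate_model(STATUS_MIX_BLOCKS if preset != "figure1" else {Status.A: 2, Status.B: 1})
    truth.true_statuses = model_truth.true_statuses
    write_model(model, out_dir / "model.xml")

    with open(out_dir / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump({
            "true_partition": {str(k): [list(r) for r in v] for k, v in truth.true_partition.items()},
            "planted_conflicts": [list(c) for c in truth.planted_conflicts],
            "true_statuses": {k: v.value for k, v in truth.true_statuses.items()},
        }, fh, indent=1, sort_keys=True)
    return truth
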