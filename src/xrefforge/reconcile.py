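"""Unified metabolite namespace construction.

Source namespaces each contribute metabolites (possibly with an InChI) and
reactions with cross-references to equivalent reactions in *other* sources.
Three evidence passes, run strictly in order and each to a fixed point,
grow a union-find partition of all source metabolites:

1. identical structure keys (protonation/isotope-insensitive, stereo kept);
2. stereo-relaxed structure match of the single unmatched metabolite pair
   in a cross-referenced reaction pair (reaction context);
3. shared normalized name of such a pair when at least one member has no
   structure at all.

Imported metabolite-to-metabolite cross-references are deliberately never
consulted: they are a known vector for propagating upstream database errors.

Conflicts (two members of one merge set on opposite sides of a reaction —
acid/base or tautomer pairs — and contradictory fully-specified stereo) are
detected and reported for curation; by default they do not block the merge.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

from .chemcore import (
    DEFAULT_POLICY,
    SimilarityVerdict,
    StructureKey,
    StructureKeyPolicy,
    parse_inchi,
    similar_structures,
    structure_key,
)
from .reacspace import Direction, Equation, Term

logger = logging.getLogger(__name__)

__all__ = [
    "MetRef",
    "SourceMetabolite",
    "SourceReaction",
    "EvidenceKind",
    "Evidence",
    "ConflictKind",
    "Resolution",
    "Conflict",
    "MergePartition",
    "NamespaceEntry",
    "normalize_name",
    "merge_identical_structures",
    "candidate_pairs_from_context",
    "apply_context_merges",
    "run_context_pass",
    "detect_conflicts",
    "select_reference",
    "assign_ids",
    "reconcile_sources",
    "DEFAULT_PRIORITY",
]

MetRef = tuple[str, str]

DEFAULT_PRIORITY = [
    "chebi", "metacycM", "keggC", "biggM", "seedM", "hmdb", "sabiorkM",
    "lipidmaps", "slm", "reactome", "envipath", "rheaG", "rheaP",
]

RESERVED_BALANCE_PROTON = "MNXM1"
RESERVED_TRANSPORT_PROTON = "MNXM01"


@dataclass(frozen=True)
class SourceMetabolite:
    prefix: str
    local_id: str
    names: tuple[str, ...] = ()
    formula: str | None = None
    charge: int | None = None
    inchi: str | None = None
    # metabolite-to-metabolite cross-references are carried for provenance
    # but NEVER consulted by the reconciliation
    xrefs: tuple[MetRef, ...] = ()

    @property
    def ref(self) -> MetRef:
        return (self.prefix, self.local_id)


@dataclass(frozen=True)
class SourceReaction:
    prefix: str
    local_id: str
    equation: Equation
    direction: Direction = Direction.LR
    xrefs: tuple[tuple[str, str], ...] = ()

    @property
    def ref(self) -> tuple[str, str]:
        return (self.prefix, self.local_id)


class EvidenceKind(Enum):
    IDENTICAL_STRUCTURE = "IDENTICAL_STRUCTURE"
    CONTEXT_STRUCTURE = "CONTEXT_STRUCTURE"
    CONTEXT_NAME = "CONTEXT_NAME"


@dataclass(frozen=True)
class Evidence:
    kind: EvidenceKind
    pair: tuple[MetRef, MetRef]
    context: tuple[tuple[str, str], tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        if self.kind is EvidenceKind.IDENTICAL_STRUCTURE and self.context is not None:
            raise ValueError("IDENTICAL_STRUCTURE evidence never carries a context")
        if self.kind is not EvidenceKind.IDENTICAL_STRUCTURE and self.context is None:
            raise ValueError(f"{self.kind.name} evidence requires a reaction context")


class ConflictKind(Enum):
    SAME_REACTION_SIDES = "SAME_REACTION_SIDES"
    STEREO_AMBIGUITY = "STEREO_AMBIGUITY"
    NAME_CLASH = "NAME_CLASH"


class Resolution(Enum):
    PENDING = "PENDING"
    ACCEPTED = "ACCEPTED"
    REJECTED = "REJECTED"


@dataclass
class Conflict:
    kind: ConflictKind
    members: frozenset[MetRef]
    reaction: tuple[str, str] | None = None
    resolution: Resolution = Resolution.PENDING

    def __post_init__(self) -> None:
        if self.kind is ConflictKind.SAME_REACTION_SIDES and self.reaction is None:
            raise ValueError("SAME_REACTION_SIDES conflicts must name the reaction")


class MergePartition:
    """Union-find over source metabolite refs with an evidence log."""

    def __init__(self, refs: Iterable[MetRef]):
        self._parent: dict[MetRef, MetRef] = {r: r for r in refs}
        if len(self._parent) == 0:
            pass
        self.evidence: list[Evidence] = []
        self.conflicts: list[Conflict] = []
        self._n_unions = 0

    def __contains__(self, ref: MetRef) -> bool:
        return ref in self._parent

    def find(self, ref: MetRef) -> MetRef:
        root = ref
        while self._parent[root] != root:
            root = self._parent[root]
        while self._parent[ref] != root:  # path compression
            self._parent[ref], ref = root, self._parent[ref]
        return root

    def union(self, a: MetRef, b: MetRef, evidence: Evidence) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        # deterministic root: lexicographically smallest ref wins
        if rb < ra:
            ra, rb = rb, ra
        self._parent[rb] = ra
        self.evidence.append(evidence)
        self._n_unions += 1
        return True

    @property
    def n_unions(self) -> int:
        return self._n_unions

    def sets(self) -> list[frozenset[MetRef]]:
        acc: dict[MetRef, set[MetRef]] = {}
        for ref in self._parent:
            acc.setdefault(self.find(ref), set()).add(ref)
        return [frozenset(s) for _, s in sorted(acc.items())]

    def merged_pairs(self) -> set[frozenset[MetRef]]:
        pairs: set[frozenset[MetRef]] = set()
        for s in self.sets():
            members = sorted(s)
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    pairs.add(frozenset((a, b)))
        return pairs

    def rejected_pairs(self) -> set[frozenset[MetRef]]:
        return {
            c.members for c in self.conflicts if c.resolution is Resolution.REJECTED
        }


_NAME_JUNK = re.compile(r"[\s\-_,;:.'\"()\[\]]+")


def normalize_name(name: str) -> str:
    """Case-fold and collapse whitespace/punctuation for exact name matching."""
    return _NAME_JUNK.sub("", name.casefold())


def _keys_by_ref(
    metabolites: Iterable[SourceMetabolite], policy: StructureKeyPolicy
) -> dict[MetRef, StructureKey]:
    keys: dict[MetRef, StructureKey] = {}
    for m in metabolites:
        if m.inchi is not None:
            keys[m.ref] = structure_key(parse_inchi(m.inchi), policy)
    return keys


def merge_identical_structures(
    metabolites: list[SourceMetabolite],
    policy: StructureKeyPolicy = DEFAULT_POLICY,
) -> MergePartition:
    """Evidence pass 1: merge metabolites with equal structure keys.

    Metabolites without a structure stay singletons — names alone never
    merge anything in this pass.
    """
    seen: set[MetRef] = set()
    for m in metabolites:
        if m.ref in seen:
            raise ValueError(f"duplicate source metabolite {m.ref}")
        seen.add(m.ref)
    partition = MergePartition(m.ref for m in metabolites)
    keys = _keys_by_ref(metabolites, policy)
    by_key: dict[tuple[str, str], list[MetRef]] = {}
    for ref in sorted(keys):
        k = keys[ref]
        by_key.setdefault((k.skeleton, k.stereo), []).append(ref)
    for _, refs in sorted(by_key.items()):
        anchor = refs[0]
        for other in refs[1:]:
            partition.union(
                anchor, other,
                Evidence(EvidenceKind.IDENTICAL_STRUCTURE, (anchor, other)),
            )
    return partition


def _class_sides(
    reaction: SourceReaction, partition: MergePartition
) -> tuple[dict, dict]:
    """Each side as {(class id, compartment): (coeff, representative ref)}."""
    out = []
    for side in (reaction.equation.left, reaction.equation.right):
        acc: dict = {}
        for t in side:
            ref = (reaction.prefix, t.met)
            if ref not in partition:
                raise KeyError(f"unresolvable metabolite reference {ref} in reaction {reaction.ref}")
            cls = partition.find(ref)
            key = (cls, t.compartment)
            coeff, _ = acc.get(key, (0, ref))
            acc[key] = (coeff + t.coeff, ref)
        out.append(acc)
    return out[0], out[1]


def _align_sides(d1: dict, d2: dict):
    """Return the unmatched (ref1, ref2) pair for one side, or None/False.

    None   — sides identical (nothing unmatched);
    False  — sides cannot be aligned (>1 unmatched, or coefficient mismatch);
    (a, b) — exactly one unmatched term per side with equal coefficients.
    """
    only1 = {k: v for k, v in d1.items() if k not in d2}
    only2 = {k: v for k, v in d2.items() if k not in d1}
    for k in set(d1) & set(d2):
        if d1[k][0] != d2[k][0]:
            return False
    if not only1 and not only2:
        return None
    if len(only1) != 1 or len(only2) != 1:
        return False
    (k1, (c1, ref1)), = only1.items()
    (k2, (c2, ref2)), = only2.items()
    if c1 != c2 or k1[1] != k2[1]:  # coefficient or compartment mismatch
        return False
    return (ref1, ref2)


def candidate_pairs_from_context(
    r1: SourceReaction,
    r2: SourceReaction,
    partition: MergePartition,
) -> list[tuple[MetRef, MetRef, str]]:
    """Metabolite pairs left unmatched when two cross-referenced reactions
    are rewritten under the current partition.

    The two equations must become identical except for at most one unmatched
    term per side, with equal coefficients.  Both relative orientations are
    tried when either reaction is bidirectional; a unique consistent
    orientation is required.
    """
    l1, r1s = _class_sides(r1, partition)
    l2, r2s = _class_sides(r2, partition)

    orientations: list[bool]
    if r1.direction is Direction.BIDIRECTIONAL or r2.direction is Direction.BIDIRECTIONAL:
        orientations = [False, True]
    elif r1.direction != r2.direction:
        orientations = [True]
    else:
        orientations = [False]

    results = []
    for flip in orientations:
        a2, b2 = (r2s, l2) if flip else (l2, r2s)
        left_pair = _align_sides(l1, a2)
        right_pair = _align_sides(r1s, b2)
        if left_pair is False or right_pair is False:
            continue
        pairs = []
        if left_pair:
            pairs.append((left_pair[0], left_pair[1], "left"))
        if right_pair:
            pairs.append((right_pair[0], right_pair[1], "right"))
        results.append(pairs)

    nonempty = [p for p in results if p]
    if len(nonempty) == 1:
        return nonempty[0]
    if len(nonempty) == 2 and nonempty[0] == nonempty[1]:
        return nonempty[0]
    return []


def _would_conflict(
    a: MetRef, b: MetRef, partition: MergePartition,
    sides_index: dict[MetRef, list[tuple[tuple[str, str], str]]],
) -> tuple[str, str] | None:
    """Reaction in which merging class(a) with class(b) spans both sides."""
    ca, cb = partition.find(a), partition.find(b)
    occ_a = {(rxn, side) for ref, occs in sides_index.items()
             if partition.find(ref) == ca for rxn, side in occs}
    occ_b = {(rxn, side) for ref, occs in sides_index.items()
             if partition.find(ref) == cb for rxn, side in occs}
    for rxn, side in occ_a:
        other = "right" if side == "left" else "left"
        if (rxn, other) in occ_b:
            return rxn
    return None


def apply_context_merges(
    partition: MergePartition,
    pairs: list[tuple[MetRef, MetRef, str]],
    metabolites: dict[MetRef, SourceMetabolite],
    kind: EvidenceKind,
    context: tuple[tuple[str, str], tuple[str, str]],
    keys: dict[MetRef, StructureKey],
    strict_sides_index: dict | None = None,
) -> int:
    """Apply one batch of context candidates under the rules of one pass.

    Pass 2 (CONTEXT_STRUCTURE) merges a pair iff its structure keys are
    STEREO_RELAXED-similar; conflicting fully-specified stereo records a
    STEREO_AMBIGUITY conflict instead.  Pass 3 (CONTEXT_NAME) merges iff at
    least one member lacks a structure and the two share a normalized name.
    Pairs previously REJECTED by curation are skipped and logged.
    Returns the number of new unions.
    """
    rejected = partition.rejected_pairs()
    merged = 0
    for a, b, _side in pairs:
        ca, cb = partition.find(a), partition.find(b)
        if ca == cb:
            continue
        if frozenset((a, b)) in rejected or frozenset((ca, cb)) in rejected:
            logger.info("skipping REJECTED pair %s / %s", a, b)
            continue
        ok = False
        if kind is EvidenceKind.CONTEXT_STRUCTURE:
            ka, kb = keys.get(a), keys.get(b)
            if ka is not None and kb is not None:
                verdict = similar_structures(ka, kb)
                if verdict is SimilarityVerdict.STEREO_RELAXED:
                    ok = True
                elif (
                    verdict is SimilarityVerdict.DIFFERENT
                    and ka.skeleton == kb.skeleton
                ):
                    partition.conflicts.append(Conflict(
                        ConflictKind.STEREO_AMBIGUITY, frozenset((a, b)),
                        reaction=context[0],
                    ))
        elif kind is EvidenceKind.CONTEXT_NAME:
            ma, mb = metabolites[a], metabolites[b]
            if ma.inchi is None or mb.inchi is None:
                na = {normalize_name(n) for n in ma.names}
                nb = {normalize_name(n) for n in mb.names}
                if na & nb:
                    ok = True
        else:
            raise ValueError(f"context pass cannot log {kind.name} evidence")
        if not ok:
            continue
        if strict_sides_index is not None:
            rxn = _would_conflict(a, b, partition, strict_sides_index)
            if rxn is not None:
                partition.conflicts.append(Conflict(
                    ConflictKind.SAME_REACTION_SIDES, frozenset((a, b)),
                    reaction=rxn, resolution=Resolution.REJECTED,
                ))
                logger.info("strict mode: rejecting merge %s / %s (reaction %s)", a, b, rxn)
                continue
        if partition.union(a, b, Evidence(kind, (a, b), context)):
            merged += 1
    return merged


def _xref_reaction_pairs(reactions: list[SourceReaction]):
    index = {r.ref: r for r in reactions}
    seen = set()
    for r in reactions:
        for xref in r.xrefs:
            if xref[0] == r.prefix:
                raise ValueError(
                    f"reaction xref {xref} points into its own namespace (from {r.ref})"
                )
            other = index.get(xref)
            if other is None:
                continue
            pair = tuple(sorted((r.ref, other.ref)))
            if pair in seen:
                continue
            seen.add(pair)
            yield index[pair[0]], index[pair[1]]


def run_context_pass(
    partition: MergePartition,
    reactions: list[SourceReaction],
    metabolites: dict[MetRef, SourceMetabolite],
    kind: EvidenceKind,
    keys: dict[MetRef, StructureKey],
    strict: bool = False,
) -> int:
    """Run one context evidence pass to a fixed point."""
    sides_index: dict | None = None
    if strict:
        sides_index = {}
        for r in reactions:
            for side_name, side in (("left", r.equation.left), ("right", r.equation.right)):
                for t in side:
                    sides_index.setdefault((r.prefix, t.met), []).append((r.ref, side_name))
    total = 0
    while True:
        merged = 0
        for ra, rb in _xref_reaction_pairs(reactions):
            pairs = candidate_pairs_from_context(ra, rb, partition)
            if pairs:
                merged += apply_context_merges(
                    partition, pairs, metabolites, kind,
                    (ra.ref, rb.ref), keys, sides_index,
                )
        total += merged
        if merged == 0:
            return total


def detect_conflicts(
    partition: MergePartition,
    reactions: list[SourceReaction],
    accepted_classes: frozenset[MetRef] = frozenset(),
) -> list[Conflict]:
    """Flag merge sets spanning both sides of a single reaction.

    Acid/base and tautomer pairs can be validly merged (yielding an empty
    reaction); a whitelist of class roots marks such conflicts ACCEPTED,
    which silences the flag but keeps the log entry.
    """
    conflicts = []
    for r in reactions:
        left_classes: dict[MetRef, set[MetRef]] = {}
        right_classes: dict[MetRef, set[MetRef]] = {}
        for acc, side in ((left_classes, r.equation.left), (right_classes, r.equation.right)):
            for t in side:
                ref = (r.prefix, t.met)
                if ref in partition:
                    acc.setdefault(partition.find(ref), set()).add(ref)
        for cls in sorted(set(left_classes) & set(right_classes)):
            members = frozenset(left_classes[cls] | right_classes[cls])
            resolution = Resolution.ACCEPTED if cls in accepted_classes else Resolution.PENDING
            conflicts.append(Conflict(
                ConflictKind.SAME_REACTION_SIDES, members,
                reaction=r.ref, resolution=resolution,
            ))
    return conflicts


def select_reference(
    entry_members: list[SourceMetabolite],
    rhea_chebi_ids: frozenset[str] = frozenset(),
    priority: list[str] | None = None,
) -> MetRef:
    """Pick the reference member of a merge set.

    Order: (1) a chebi member cited by a Rhea reaction; (2) the
    earliest-priority member that has a structure; (3) the earliest-priority
    member regardless; ties always broken by smallest (prefix, local_id).
    """
    if not entry_members:
        raise ValueError("cannot select a reference from an empty member set")
    priority = DEFAULT_PRIORITY if priority is None else priority

    def prio(m: SourceMetabolite) -> tuple:
        try:
            p = priority.index(m.prefix)
        except ValueError:
            p = len(priority)
        return (p, m.prefix, m.local_id)

    rhea_chebi = [
        m for m in entry_members if m.prefix == "chebi" and m.local_id in rhea_chebi_ids
    ]
    if rhea_chebi:
        return min(rhea_chebi, key=prio).ref
    structured = [m for m in entry_members if m.inchi is not None]
    if structured:
        return min(structured, key=prio).ref
    return min(entry_members, key=prio).ref


@dataclass
class NamespaceEntry:
    mnx_id: str
    members: frozenset[MetRef]
    reference: MetRef
    structure: str | None
    name: str
    formula: str | None = None
    charge: int | None = None


def _reserved_entries() -> list[NamespaceEntry]:
    return [
        NamespaceEntry(
            mnx_id=RESERVED_BALANCE_PROTON, members=frozenset(),
            reference=("mnx", "MNXM1"), structure="InChI=1S/p+1",
            name="H(+)", formula="H", charge=1,
        ),
        NamespaceEntry(
            mnx_id=RESERVED_TRANSPORT_PROTON, members=frozenset(),
            reference=("mnx", "MNXM01"), structure="InChI=1S/p+1",
            name="H(+) (transported)", formula="H", charge=1,
        ),
    ]


def assign_ids(
    partition: MergePartition,
    references: dict[frozenset[MetRef], MetRef],
    metabolites: dict[MetRef, SourceMetabolite] | None = None,
) -> list[NamespaceEntry]:
    """Assign deterministic MNXM ids to the partition's merge sets.

    Ids are "MNXM" + the next zero-free integer (no '0' digit, so MNXM1 and
    MNXM01 can never collide with a generated id), assigned in sorted order
    of the reference (prefix, local_id).  The two reserved proton entries
    are always emitted first.
    """
    metabolites = metabolites or {}
    from .reacspace import _zero_free_ids  # shared id scheme

    sets = partition.sets()
    ordered = sorted(sets, key=lambda s: references[s])
    ids = _zero_free_ids(
        "MNXM", len(ordered),
        frozenset((RESERVED_BALANCE_PROTON, RESERVED_TRANSPORT_PROTON)),
    )
    entries = _reserved_entries()
    for mnx_id, members in zip(ids, ordered):
        ref = references[members]
        if ref not in members:
            raise ValueError(f"reference {ref} is not a member of its set")
        refmet = metabolites.get(ref)
        entries.append(NamespaceEntry(
            mnx_id=mnx_id,
            members=members,
            reference=ref,
            structure=refmet.inchi if refmet else None,
            name=(refmet.names[0] if refmet and refmet.names else ref[1]),
            formula=refmet.formula if refmet else None,
            charge=refmet.charge if refmet else None,
        ))
    return entries


def reconcile_sources(
    metabolites: list[SourceMetabolite],
    reactions: list[SourceReaction],
    *,
    policy: StructureKeyPolicy = DEFAULT_POLICY,
    priority: list[str] | None = None,
    rhea_chebi_ids: frozenset[str] = frozenset(),
    accepted_classes: frozenset[MetRef] = frozenset(),
    strict_conflicts: bool = False,
) -> tuple[list[NamespaceEntry], MergePartition]:
    """Full three-pass reconciliation of a source corpus.

    Returns the namespace entries (reserved protons first, then MNXM ids in
    deterministic order) and the final partition with its evidence log and
    conflicts.  Metabolite-to-metabolite xrefs present in the inputs are
    ignored throughout.
    """
    met_index = {m.ref: m for m in metabolites}
    partition = merge_identical_structures(metabolites, policy)
    keys = _keys_by_ref(metabolites, policy)
    run_context_pass(
        partition, reactions, met_index, EvidenceKind.CONTEXT_STRUCTURE,
        keys, strict=strict_conflicts,
    )
    run_context_pass(
        partition, reactions, met_index, EvidenceKind.CONTEXT_NAME,
        keys, strict=strict_conflicts,
    )
    partition.conflicts.extend(detect_conflicts(partition, reactions, accepted_classes))
    references = {
        s: select_reference([met_index[r] for r in sorted(s)], rhea_chebi_ids, priority)
        for s in partition.sets()
    }
    entries = assign_ids(partition, references, met_index)
    return entries, partition
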