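"""Evidence passes, conflicts, reference selection and id assignment."""

from __future__ import annotations

import dataclasses
from fractions import Fraction

import pytest

from xrefforge.fixtures import DEFAULT_CONFIG, generate_sources
from xrefforge.reacspace import Direction, Equation, Term
from xrefforge.reconcile import (
    Conflict,
    ConflictKind,
    EvidenceKind,
    Resolution,
    SourceMetabolite,
    SourceReaction,
    assign_ids,
    candidate_pairs_from_context,
    detect_conflicts,
    merge_identical_structures,
    normalize_name,
    reconcile_sources,
    select_reference,
)

F = Fraction

ACETIC = "InChI=1S/C2H4O2/c1-2(3)4/h1H3,(H,3,4)"
ACETATE = ACETIC + "/p-1"
L_ALA = "InChI=1S/C3H7NO2/c1-2(4)3(5)6/h2H,4H2,1H3,(H,5,6)/t2-/m0/s1"
D_ALA = "InChI=1S/C3H7NO2/c1-2(4)3(5)6/h2H,4H2,1H3,(H,5,6)/t2-/m1/s1"
ALA = "InChI=1S/C3H7NO2/c1-2(4)3(5)6/h2H,4H2,1H3,(H,5,6)"


def met(prefix, lid, inchi=None, names=(), formula=None, charge=None):
    return SourceMetabolite(prefix, lid, tuple(names), formula, charge, inchi)


def rxn(prefix, lid, left, right, direction=Direction.LR, xrefs=()):
    side = lambda terms: tuple(Term(m, F(c)) for m, c in terms)
    return SourceReaction(
        prefix, lid, Equation(side(left), side(right), direction), direction, tuple(xrefs)
    )


class TestPass1:
    def test_protonation_variants_merge(self):
        mets = [met("dbA", "x", ACETATE), met("dbB", "y", ACETIC)]
        partition = merge_identical_structures(mets)
        assert partition.sets() == [frozenset({("dbA", "x"), ("dbB", "y")})]
        assert [e.kind for e in partition.evidence] == [EvidenceKind.IDENTICAL_STRUCTURE]

    def test_names_alone_never_merge(self):
        mets = [met("dbA", "x", names=["water"]), met("dbB", "y", names=["water"])]
        partition = merge_identical_structures(mets)
        assert len(partition.sets()) == 2
        assert partition.evidence == []

    def test_duplicate_ref_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            merge_identical_structures([met("a", "x"), met("a", "x")])

    def test_ground_truth_partition_recovered(self):
        """Protonation-only perturbation: pass 1 alone recovers the full
        generator partition (structure keys ignore /p and charge)."""
        cfg = dataclasses.replace(
            DEFAULT_CONFIG, structure_dropout=0.0, stereo_erase=0.0,
            protonation_perturb=0.5, n_acid_base=0, seed=11,
        )
        mets, _, truth = generate_sources(cfg)
        partition = merge_identical_structures(mets)
        got = {s for s in partition.sets() if len(s) > 1}
        want = {frozenset(refs) for refs in truth.true_partition.values() if len(refs) > 1}
        assert got == want
        assert len(got) == cfg.n_true_compounds


class TestContextCandidates:
    def _abc_setup(self):
        mets = [
            met("s1", "A", "InChI=1S/CH4/h1H4"),
            met("s1", "B", names=["beta"]),
            met("s1", "C", "InChI=1S/H2O/h1H2"),
            met("s2", "A", "InChI=1S/CH4/h1H4"),
            met("s2", "B2", names=["beta"]),
            met("s2", "C", "InChI=1S/H2O/h1H2"),
        ]
        partition = merge_identical_structures(mets)
        return mets, partition

    def test_single_unmatched_pair(self):
        _, partition = self._abc_setup()
        r1 = rxn("s1", "r1", [("A", 1), ("B", 1)], [("C", 1)])
        r2 = rxn("s2", "r2", [("A", 1), ("B2", 1)], [("C", 1)], xrefs=[("s1", "r1")])
        pairs = candidate_pairs_from_context(r1, r2, partition)
        assert pairs == [(("s1", "B"), ("s2", "B2"), "left")]

    def test_one_pair_per_side(self):
        mets = [
            met("s1", "A", "InChI=1S/CH4/h1H4"), met("s1", "B"), met("s1", "C"),
            met("s2", "A", "InChI=1S/CH4/h1H4"), met("s2", "B2"), met("s2", "C2"),
        ]
        partition = merge_identical_structures(mets)
        r1 = rxn("s1", "r1", [("A", 1), ("B", 1)], [("C", 1)])
        r2 = rxn("s2", "r2", [("A", 1), ("B2", 1)], [("C2", 1)], xrefs=[("s1", "r1")])
        pairs = candidate_pairs_from_context(r1, r2, partition)
        assert set(pairs) == {
            (("s1", "B"), ("s2", "B2"), "left"),
            (("s1", "C"), ("s2", "C2"), "right"),
        }

    def test_coefficient_mismatch_blocks(self):
        _, partition = self._abc_setup()
        r1 = rxn("s1", "r1", [("A", 1), ("B", 1)], [("C", 1)])
        r2 = rxn("s2", "r2", [("A", 1), ("B2", 2)], [("C", 1)], xrefs=[("s1", "r1")])
        assert candidate_pairs_from_context(r1, r2, partition) == []

    def test_two_unmatched_same_side_blocks(self):
        mets = [
            met("s1", "A"), met("s1", "B"), met("s1", "C", "InChI=1S/H2O/h1H2"),
            met("s2", "A2"), met("s2", "B2"), met("s2", "C", "InChI=1S/H2O/h1H2"),
        ]
        partition = merge_identical_structures(mets)
        r1 = rxn("s1", "r1", [("A", 1), ("B", 1)], [("C", 1)])
        r2 = rxn("s2", "r2", [("A2", 1), ("B2", 1)], [("C", 1)], xrefs=[("s1", "r1")])
        assert candidate_pairs_from_context(r1, r2, partition) == []

    def test_bidirectional_tries_flip(self):
        _, partition = self._abc_setup()
        r1 = rxn("s1", "r1", [("A", 1), ("B", 1)], [("C", 1)], Direction.BIDIRECTIONAL)
        r2 = rxn("s2", "r2", [("C", 1)], [("A", 1), ("B2", 1)],
                 Direction.BIDIRECTIONAL, xrefs=[("s1", "r1")])
        pairs = candidate_pairs_from_context(r1, r2, partition)
        assert pairs == [(("s1", "B"), ("s2", "B2"), "left")]

    def test_unresolvable_reference_errors(self):
        _, partition = self._abc_setup()
        r1 = rxn("s1", "r1", [("ZZZ", 1)], [("C", 1)])
        r2 = rxn("s2", "r2", [("A", 1)], [("C", 1)], xrefs=[("s1", "r1")])
        with pytest.raises(KeyError):
            candidate_pairs_from_context(r1, r2, partition)


class TestFullReconciliation:
    def _corpus(self):
        mets = [
            met("s1", "LALA", L_ALA, ["L-alanine"]),
            met("s1", "W", "InChI=1S/H2O/h1H2", ["water"]),
            met("s1", "F", "InChI=1S/CH4/h1H4", ["Fumarate"]),
            met("s2", "ALA", ALA, ["alanine"]),
            met("s2", "W", "InChI=1S/H2O/h1H2", ["water"]),
            met("s2", "FUM", None, ["fumarate"]),
        ]
        rxns = [
            rxn("s1", "r1", [("LALA", 1)], [("W", 1), ("F", 1)]),
            rxn("s2", "r2", [("ALA", 1)], [("W", 1), ("FUM", 1)], xrefs=[("s1", "r1")]),
        ]
        return mets, rxns

    def test_stereo_relaxed_context_merge(self):
        mets, rxns = self._corpus()
        _, partition = reconcile_sources(mets, rxns)
        classes = {frozenset(s) for s in partition.sets() if len(s) > 1}
        assert frozenset({("s1", "LALA"), ("s2", "ALA")}) in classes
        kinds = [e.kind for e in partition.evidence]
        assert EvidenceKind.CONTEXT_STRUCTURE in kinds

    def test_name_context_merge_requires_missing_structure(self):
        mets, rxns = self._corpus()
        _, partition = reconcile_sources(mets, rxns)
        classes = {frozenset(s) for s in partition.sets() if len(s) > 1}
        assert frozenset({("s1", "F"), ("s2", "FUM")}) in classes
        name_ev = [e for e in partition.evidence if e.kind is EvidenceKind.CONTEXT_NAME]
        assert all(e.context is not None for e in name_ev)

    def test_conflicting_stereo_never_merged(self):
        mets = [
            met("s1", "L", L_ALA, ["alanine"]),
            met("s1", "W", "InChI=1S/H2O/h1H2"),
            met("s2", "D", D_ALA, ["alanine"]),
            met("s2", "W", "InChI=1S/H2O/h1H2"),
        ]
        rxns = [
            rxn("s1", "r1", [("L", 1)], [("W", 1)]),
            rxn("s2", "r2", [("D", 1)], [("W", 1)], xrefs=[("s1", "r1")]),
        ]
        _, partition = reconcile_sources(mets, rxns)
        assert all(len(s) == 1 for s in partition.sets() if ("s1", "L") in s)
        assert any(c.kind is ConflictKind.STEREO_AMBIGUITY for c in partition.conflicts)

    def test_structures_win_over_names(self):
        """Name evidence must not merge two structure-bearing metabolites
        whose structures differ."""
        mets = [
            met("s1", "X", "InChI=1S/CH4/h1H4", ["widget"]),
            met("s1", "W", "InChI=1S/H2O/h1H2"),
            met("s2", "Y", "InChI=1S/C2H6/c1-2/h1-2H3", ["widget"]),
            met("s2", "W", "InChI=1S/H2O/h1H2"),
        ]
        rxns = [
            rxn("s1", "r1", [("X", 1)], [("W", 1)]),
            rxn("s2", "r2", [("Y", 1)], [("W", 1)], xrefs=[("s1", "r1")]),
        ]
        _, partition = reconcile_sources(mets, rxns)
        assert partition.find(("s1", "X")) != partition.find(("s2", "Y"))

    def test_metabolite_xrefs_are_ignored(self):
        """Adversarial metabolite-to-metabolite xrefs change nothing."""
        mets, rxns = self._corpus()
        entries1, p1 = reconcile_sources(mets, rxns)
        poisoned = [
            dataclasses.replace(
                m, xrefs=((("s2" if m.prefix == "s1" else "s1"), "W"),)
            )
            for m in mets
        ]
        entries2, p2 = reconcile_sources(poisoned, rxns)
        assert p1.sets() == p2.sets()
        assert [(e.mnx_id, e.members) for e in entries1] == [
            (e.mnx_id, e.members) for e in entries2
        ]

    def test_idempotence(self):
        """Reconciling the reconciled namespace yields only singletons."""
        mets, rxns = self._corpus()
        entries, _ = reconcile_sources(mets, rxns)
        remets = [
            met("mnx", e.mnx_id, e.structure, [e.name]) for e in entries if e.members
        ]
        _, partition = reconcile_sources(remets, [])
        assert all(len(s) == 1 for s in partition.sets())

    def test_monotone_passes(self):
        """Each pass only adds merged pairs on top of the previous one."""
        mets, rxns, _ = generate_sources(dataclasses.replace(DEFAULT_CONFIG, seed=5))
        from xrefforge.reconcile import _keys_by_ref, run_context_pass
        from xrefforge.chemcore import DEFAULT_POLICY

        met_index = {m.ref: m for m in mets}
        partition = merge_identical_structures(mets)
        after1 = partition.merged_pairs()
        keys = _keys_by_ref(mets, DEFAULT_POLICY)
        run_context_pass(partition, rxns, met_index, EvidenceKind.CONTEXT_STRUCTURE, keys)
        after2 = partition.merged_pairs()
        run_context_pass(partition, rxns, met_index, EvidenceKind.CONTEXT_NAME, keys)
        after3 = partition.merged_pairs()
        assert after1 <= after2 <= after3


class TestConflicts:
    def test_same_reaction_sides_flagged(self):
        mets = [met("s1", "acid", ACETIC), met("s1", "base", ACETATE)]
        partition = merge_identical_structures(mets)
        reactions = [rxn("s1", "r", [("acid", 1)], [("base", 1)])]
        conflicts = detect_conflicts(partition, reactions)
        assert len(conflicts) == 1
        c = conflicts[0]
        assert c.kind is ConflictKind.SAME_REACTION_SIDES
        assert c.reaction == ("s1", "r")
        assert c.resolution is Resolution.PENDING

    def test_no_spanning_set_no_conflict(self):
        mets = [met("s1", "a", ACETIC), met("s1", "b", "InChI=1S/H2O/h1H2")]
        partition = merge_identical_structures(mets)
        reactions = [rxn("s1", "r", [("a", 1)], [("b", 1)])]
        assert detect_conflicts(partition, reactions) == []

    def test_whitelist_marks_accepted(self):
        mets = [met("s1", "acid", ACETIC), met("s1", "base", ACETATE)]
        partition = merge_identical_structures(mets)
        reactions = [rxn("s1", "r", [("acid", 1)], [("base", 1)])]
        root = partition.find(("s1", "acid"))
        conflicts = detect_conflicts(partition, reactions, frozenset({root}))
        assert conflicts[0].resolution is Resolution.ACCEPTED

    def test_planted_conflicts_found_exactly(self):
        mets, rxns, truth = generate_sources(DEFAULT_CONFIG)
        _, partition = reconcile_sources(mets, rxns)
        flagged = {
            c.reaction for c in partition.conflicts
            if c.kind is ConflictKind.SAME_REACTION_SIDES
        }
        assert flagged == set(truth.planted_conflicts)
        assert len(flagged) == DEFAULT_CONFIG.n_acid_base

    def test_strict_mode_blocks_context_merge(self):
        """In strict mode a context merge that would span a reaction's sides
        is rejected and logged instead of applied."""
        mets = [
            met("s1", "P", L_ALA, ["ala"]),
            met("s1", "Q", ALA, ["ala"]),
            met("s1", "W", "InChI=1S/H2O/h1H2"),
            met("s2", "P2", L_ALA, ["ala"]),
            met("s2", "Q2", None, ["something else"]),
            met("s2", "W", "InChI=1S/H2O/h1H2"),
        ]
        # P/Q appear on both sides of r0; context pair (Q, Q2 ~ P-class)
        rxns = [
            rxn("s1", "r0", [("P", 1)], [("Q", 1)]),
            rxn("s1", "r1", [("Q", 1)], [("W", 1)]),
            rxn("s2", "r2", [("P2", 1)], [("W", 1)], xrefs=[("s1", "r1")]),
        ]
        _, loose = reconcile_sources(mets, rxns)
        merged_loose = loose.find(("s1", "Q")) == loose.find(("s2", "P2"))
        _, strict = reconcile_sources(mets, rxns, strict_conflicts=True)
        merged_strict = strict.find(("s1", "Q")) == strict.find(("s2", "P2"))
        assert merged_loose and not merged_strict
        assert any(c.resolution is Resolution.REJECTED for c in strict.conflicts)


class TestReferenceAndIds:
    def test_rhea_chebi_preferred(self):
        members = [
            met("chebi", "15377", "InChI=1S/H2O/h1H2"),
            met("keggC", "C00001", "InChI=1S/H2O/h1H2"),
        ]
        ref = select_reference(members, rhea_chebi_ids=frozenset({"15377"}))
        assert ref == ("chebi", "15377")

    def test_singleton(self):
        assert select_reference([met("seedM", "cpd00001")]) == ("seedM", "cpd00001")

    def test_tie_break_lexicographic(self):
        members = [met("chebi", "B"), met("chebi", "A")]
        ref = select_reference(members, rhea_chebi_ids=frozenset({"A", "B"}))
        assert ref == ("chebi", "A")

    def test_structure_beats_priority(self):
        members = [met("chebi", "1"), met("seedM", "2", "InChI=1S/H2O/h1H2")]
        assert select_reference(members) == ("seedM", "2")

    def test_empty_members_rejected(self):
        with pytest.raises(ValueError):
            select_reference([])

    def test_ids_ordered_by_reference(self):
        mets = [met("chebi", "100", "InChI=1S/CH4/h1H4"),
                met("chebi", "200", "InChI=1S/H2O/h1H2")]
        partition = merge_identical_structures(mets)
        refs = {s: sorted(s)[0] for s in partition.sets()}
        entries = assign_ids(partition, refs, {m.ref: m for m in mets})
        generated = [e for e in entries if e.members]
        assert [e.reference for e in generated] == [("chebi", "100"), ("chebi", "200")]
        assert [e.mnx_id for e in generated] == ["MNXM2", "MNXM3"]

    def test_reserved_ids_present_and_zero_free(self):
        partition = merge_identical_structures([])
        entries = assign_ids(partition, {})
        assert [e.mnx_id for e in entries] == ["MNXM1", "MNXM01"]

    def test_deterministic_rerun(self, default_corpus):
        mets, rxns, _ = default_corpus
        e1, _ = reconcile_sources(mets, rxns)
        e2, _ = reconcile_sources(mets, rxns)
        assert [(e.mnx_id, e.members, e.reference) for e in e1] == [
            (e.mnx_id, e.members, e.reference) for e in e2
        ]

    def test_no_zero_digit_in_generated_ids(self, default_namespace):
        entries, _ = default_namespace
        for e in entries:
            if e.members:
                assert "0" not in e.mnx_id[4:]


def test_normalize_name():
    assert normalize_name("L-Alanine") == normalize_name("l alanine")
    assert normalize_name("Fumarate") == normalize_name("fumarate")
    assert normalize_name("a b") != normalize_name("ab c")
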