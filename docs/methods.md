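# Methods

## Scope and model

`xrefforge` treats identifier reconciliation as entity resolution under a
deliberately coarse notion of identity: two database entries denote the same
metabolite if they differ at most in protonation state, formal charge,
isotopic labelling — and, when the evidence supports it, in unspecified
stereochemistry or in having no structure at all. A namespace entry is
therefore a *set* of source entries with one chosen reference; a namespace
reaction is a set of source reactions whose equations coincide after
rewriting, up to direction and scaling.

## Structure keys

Standard InChI already canonicalizes mobile-hydrogen tautomers into its
`/h` layer, so no tautomer enumeration is attempted; structures are consumed
as precomputed InChI strings (no SMILES conversion — an optional validation
hook could recompute InChIs with RDKit, but nothing depends on it). The key
of a parsed InChI under the default policy:

* Hill formula with the H token removed (heavy-atom counts kept), paired
  componentwise with the `/c` connectivity and sorted, so the component
  order of multi-component (salt) formulas is immaterial;
* `/p`, `/q`, `/i` content excluded;
* stereo descriptors (`/t /m /s /b`) concatenated and kept.

Dropping the formula's H count together with `/p` and `/q` is what makes the
key protonation-blind: adding or removing a proton changes exactly those.
The `drop_stereo` switch exists only for the context pass comparison: two
keys with equal skeletons where at least one stereo string is empty are
*stereo-relaxed* similar (an L-form with full stereo vs. the same connectivity
with none); two conflicting fully specified stereo strings are different and
are never merged automatically — that situation (L vs. D) is exactly the one
flagged for curation.

## Evidence passes

Passes run strictly in order, each to a fixed point, never interleaved.
Pass 1 groups by structure key (metabolites without structure stay
singletons; names alone never merge in pass 1). Passes 2 and 3 use *reaction
context*: for a cross-referenced reaction pair, both equations are rewritten
under the current partition; if they agree except for exactly one unmatched
term per side with equal coefficients and compartments, those term pairs are
merge candidates. Both relative orientations are tried when either reaction
is bidirectional, and a unique consistent orientation is required. Pass 2
merges stereo-relaxed candidates; pass 3 merges candidates where at least
one member lacks a structure and a case-folded, punctuation-collapsed name
matches exactly. No fuzzy or synonym name matching is done — a false merge
is far more costly than a missed one. Name evidence never overrides
structures: two structure-bearing entries with different skeletons are never
merged, whatever their names.

Metabolite-to-metabolite cross-references present in source files are parsed
(for provenance) but never consulted, to avoid importing upstream errors;
this is verified by an invariance test that injects adversarial wrong xrefs
and asserts bit-identical output.

Merge sets spanning both sides of one reaction are reported as conflicts.
They are *not* blocked by default: acid/base or tautomer pairs are valid
merges whose reactions legitimately become empty and disappear from mapped
models. `--strict-conflicts` rejects such merges instead (the conflict is
logged as REJECTED and the pair is skipped thereafter).

Reference selection: a ChEBI member cited by Rhea (the set of such ChEBI ids
is an explicit input, as sources here are self-contained), then the
earliest-priority member with a structure, then without; all ties broken by
smallest (prefix, local id). Ids are `MNXM` plus the next integer containing
no zero digit, assigned in sorted reference order — zero-free numbering keeps
the reserved pair `MNXM1` (balancing proton) and `MNXM01` (transported
proton) unambiguous forever. The numbering is deterministic from content,
not insertion order; the historical numbering of any real resource is not
reproduced.

## Reaction space

Stoichiometry is exact `Fraction` arithmetic throughout — canonical keys
must be bit-stable, and floating-point coefficients would make deduplication
seed-dependent. Rewriting substitutes ids, combines like terms within a side
and cancels the common amount of any (metabolite, compartment) pair present
on both sides; mass balance is provably unchanged by cancellation. Balance
verdicts: BALANCED, PROTON_ONLY (element delta is {H: n≠0} with charge delta
n), UNBALANCED, UNKNOWN (a participant lacks formula or charge). Only
PROTON_ONLY imbalances are repaired, by adding |n| × `MNXM1` to the deficient
side in the majority compartment; anything else is reported, never "fixed".
Transported protons: for each cross-compartment pair, min(left, right)
proton units are relabelled `MNXM01` on both sides, remainder stays `MNXM1`;
compartment pairs are processed in sorted order for determinism.

Canonical keys scale coefficients to the smallest coprime integers (LCM of
denominators, then GCD), sort terms within sides, and place the
lexicographically smaller side string left; direction is excluded from the
key and folded relative to the chosen orientation. Members of one key group
that disagree on direction yield a BIDIRECTIONAL entry — the permissive
choice; the alternative (keeping the reference's direction) would silently
forbid fluxes some source asserts. Reaction references prefer a Rhea member,
then the same priority order as metabolites.

## Model mapping

SBML Level 2 and Level 3 (FBC v2) are read through libSBML. Flux bounds come
from FBC parameters, then L2 kinetic-law `LOWER_BOUND`/`UPPER_BOUND`
parameters, then defaults by the `reversible` flag; infinities clamp to
±big-M (default 1000, the common constraint-based convention, configurable).
Species resolve by annotation (identifiers.org URIs) first, then by their
declared id read as a source cross-reference, then by exact normalized name;
first match wins and an annotation/name disagreement is logged at WARNING —
annotations are machine-curated, names are not. Unmapped species keep their
model-local ids (models legitimately contain metabolites found nowhere
else). Reactions are rewritten within the model's own compartments (source
reactions are keyed in generic compartment space; the model's compartments
are never renamed). Emptied reactions are dropped with a diagnostic; key
collisions are reported as merges, and the merged bounds are combined after
mirroring members written in the opposite orientation, so an import merged
with its matching export becomes one reversible exchange of identical
capability. Mapped models are written as SBML L3 + FBC v2 regardless of
input level.

## Flux status

The steady-state polytope is {v : S·v = 0, lb ≤ v ≤ ub}, with rows only for
non-boundary species. A reaction is a boundary (exchange) reaction when one
side of its equation is empty or contains only boundary species. "Carries
flux" in a regime means max v_r > tol or min v_r < −tol, two LPs solved with
HiGHS; regimes ORIGINAL / BOUNDARY_RELAXED / ALL_RELAXED relax nothing, the
boundary set, or every reaction to [−M, M]. Since relaxation only enlarges
the feasible set, status can only improve along A → a → b, and regimes are
evaluated lazily (at most six LPs per reaction). Defaults tol = 1e-6,
big-M = 1000, both configurable; fixture networks are built so no true range
falls inside [1e-9, 1e-5], making classifications tolerance-stable. Bounds
excluding zero (forced maintenance fluxes) are clamped to include zero with
a WARNING — the status definition presumes v = 0 feasible, and whether a
forced-flux reaction should count as A is genuinely ambiguous; clamping is
the explicit choice here.

Two exact rational oracles verify the LP path: the nullspace rank test
(v_r ≠ 0 possible in null(S) iff rank([S; e_r]) > rank(S)), which equals
ALL_RELAXED feasibility for any M > 0; and vertex enumeration of the bounded
polytope (every vertex has a basic representation fixing n − rank(S)
coordinates at bounds), giving exact min/max per reaction for networks up to
~10 reactions. Both use hand-rolled Fraction Gaussian elimination — at the
call volumes of the agreement suites, exact arithmetic on 6×8 systems must
cost microseconds, not milliseconds.

## Synthetic study conditions

The source generator emulates the statistical situation reconciliation
faces: `n_sources` = 3 namespaces each carrying a copy of every one of
`n_true_compounds` = 40 compounds, perturbed independently per copy —
structure dropped entirely with probability 0.25 (name and formula kept),
otherwise stereo erased with probability 0.25 (on the half of compounds that
carry stereo) and a ±1 protonation shift applied with probability 0.5.
Shared reactions (40, each cross-referenced to both other sources' copies)
take four distinct participants from a sliding window over a compound
permutation, so each compound appears in about four reactions — enough
context that a perturbed copy is usually the single unmatched term in some
reaction pair. Three acid/base pairs are planted in the first source to
exercise conflict detection. Synthetic InChIs come from a small valid
grammar (unique heavy-atom composition, chain connectivity, optional stereo
and protonation layers), *not* real chemistry: the generator exercises layer
handling, never chemical plausibility, and passing tests say nothing about
R-groups, polymers, or real databases' name hygiene. Compound names are
unique per compound, so merged-pair precision is structurally 100%; recall
(aggregate ≈ 98–99% over 20 seeds) is limited by copies whose every reaction
context contains a second unresolved pair on the same side — the passes
never interleave, so a stereo pair discovered after name evidence stays
unmerged.

The model generator assembles stoichiometric motifs with provable status:
hub import/export plus irreversible cycles through the hub (A); import-only
pockets that drain once an exchange may reverse (a); parallel pairs or
wrong-way triangles of internal reactions needing one reversal (b); closed
dead-end reactions (B). Motifs connect through a hub metabolite added with
equal stoichiometry to both sides of one reaction per motif — a net-zero
column entry that links the network without altering any mass-balance row.
Net coupling is avoided deliberately: status depends on whole-network
topology, and any stoichiometric bridge can flip a block's class. Two
consequences are worth knowing: an A block needs ≥ 2 reactions (import +
export), and a and b blocks compose from sizes {2, 3} — a single-reaction b
block cannot exist, since status b requires a nullspace vector through the
reaction and a closed motif only supplies one with support ≥ 2. Block sizes
keep every true flux range at 0 or ≥ 1 in magnitude, so no classification is
tolerance-marginal.

## Acceptance computation sizes

`scripts/acceptance.py` (≈ 30 s, one CPU) uses: 20 reconciliation corpora of
3 × 43 metabolites and 129 reactions; the exhaustive grid of motif networks
with ≤ 8 reactions (≈ 60 networks) against vertex enumeration under all
three regimes; 1000 random 6×8 integer stoichiometries for the nullspace/LP
cross-check (8000 reaction verdicts); 100 random block models for
monotonicity and column-rescaling invariance; and one full
write→read→write / map→status→conservation cycle. These sizes were chosen
as the smallest at which every check is exhaustive over its intended space
or statistically boring (zero violations across seeds).

## Known limitations

* Name matching is exact after normalization; synonym tables and fuzzy
  matching are out of scope, so real-world recall would be lower than the
  synthetic harness suggests.
* R-group and polymer structures are not interpreted; entries carrying them
  only ever merge on byte-identical keys.
* Gene/protein association mapping, compartment-name unification beyond
  exact labels, thermodynamic direction inference and loop-law filtering are
  out of scope.
* Secondary/deprecated identifier tracking is not implemented; the namespace
  is rebuilt from scratch each run.
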