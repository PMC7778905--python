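# xrefforge

Reconciliation of metabolite and reaction identifiers across biochemical
databases and genome-scale metabolic networks (GSMNs), with diagnostics that
verify the reconciliation preserves model properties.

## The problem

Every major biochemistry resource (ChEBI, KEGG, MetaCyc, BiGG, SEED, …) names
the same small molecules differently, and published GSMNs freely mix those
namespaces — often using bare "symbols" with no molecular structure at all.
Comparing or combining models therefore requires deciding, at scale, when two
identifiers denote the same biochemical entity. The decision is deliberately
coarse: protonation states, tautomers and isotopic labelling are folded
together, because a metabolic model does not distinguish acetate from acetic
acid. But merging metabolites merges the reactions written over them —
sometimes down to an *empty* equation — and can silently change what a model
is able to do. `xrefforge` implements both halves of the problem: building a
unified namespace from evidence, and measuring what the mapping did to a
model's flux capabilities.

## How it works

**Structure keys** (`chemcore`). Each InChI is split into layers and reduced
to a key that drops the `/p` (protonation), `/q` (charge) and `/i` (isotope)
layers and elides the hydrogen count of the formula, keeping heavy atoms,
connectivity and — by default — stereo descriptors. Equal keys are the
strongest merge evidence.

**Three evidence passes** (`reconcile`). A union–find partition over all
source metabolites grows monotonically through three passes, each run to a
fixed point before the next:

1. *identical structures* — equal structure keys;
2. *similar structures in reaction context* — two cross-referenced reactions
   whose equations, rewritten under the current partition, differ by exactly
   one metabolite pair per side with equal coefficients; the pair is merged
   when one member is a fully specified stereoisomer of the other's
   stereo-unspecified structure (conflicting stereo is never merged);
3. *structure and name in reaction context* — the same alignment, merged when
   at least one member has no structure and the two share a normalized name.

Metabolite-to-metabolite cross-references imported from the sources are
**never** consulted — they are a vector for propagating upstream errors.
Merge sets spanning both sides of one reaction (acid/base, tautomer pairs)
are flagged for curation but merged by default; `--strict-conflicts`
reverses that. Each set gets a reference member (ChEBI entries cited by Rhea
first, then a configurable source priority) and a deterministic `MNXM…` id.

**Reaction space** (`reacspace`). Equations are rewritten in namespace ids
with exact rational stoichiometry, like terms combined and shared terms
cancelled; proton-only imbalances are repaired with the balancing proton
`MNXM1`; protons crossing a compartment boundary are relabelled `MNXM01`
(proton motive force). A canonical key — sorted terms, coprime integer
coefficients, orientation-normalized — deduplicates reactions up to
direction and scaling.

**Model mapping and flux status** (`gsmnmap`, `fluxstatus`). SBML L2/L3(+FBC)
models are mapped species-by-species (annotation → id cross-reference →
normalized name), rewritten, and diagnosed: emptied reactions, merged
reactions, unmapped participants. Every reaction gets a status by a flux
variability variant (min/max of v_r over {S·v = 0, bounds}):

| status | meaning |
|--------|---------|
| `A` | carries non-zero flux under the model's own bounds |
| `a` | carries flux once all boundary (exchange) reactions are bi-directional |
| `b` | carries flux once *all* reactions are bi-directional |
| `B` | blocked by network topology (e.g. a dead-end metabolite) |

Status profiles before and after mapping are compared; a conserved profile is
evidence the reconciliation did not distort the model. Exact rational oracles
(`exact`: rank/nullspace tests and vertex enumeration of the flux polytope)
independently verify the LP classifier on small networks.

## Worked example

The bundled `figure1` preset is the classic progressive-reconciliation
situation: five source metabolites in four cross-referenced reactions.

```bash
xref-forge fixtures --preset figure1 --seed 1 --out demo/fx
xref-forge reconcile --sources demo/fx/sources --out demo/ns
# INFO xrefforge: namespace: 2 metabolite entries, 1 reaction entries (0 empty)
cat demo/ns/chem_prop.tsv
# #ID     name                reference  formula  charge  InChI
# MNXM1   H(+)                mnx:MNXM1  H        1       InChI=1S/p+1
# MNXM01  H(+) (transported)  mnx:MNXM01 H        1       InChI=1S/p+1
# MNXM2   L-widgetine         S0:A0      C2H6O    0       InChI=1S/C2H6O/c1-2-3/h1-2H2/t2-/m0/s1
# MNXM3   gadgetol            S0:B0      C2H6O2   0       InChI=1S/C2H6O2/c1-2-3-4/h1-2H2
cat demo/ns/reac_prop.tsv
# #ID     equation        direction  reference
# MNXR2   MNXM2 = MNXM3   B          S0:r0
```

The five metabolites collapsed to two entries — one merge per evidence pass
(identical structure, stereo-relaxed structure in context, shared name in
context) — and the four reactions to a single bidirectional one. Flux status
of the preset's toy model:

```bash
xref-forge status --model demo/fx/model.xml --out demo/status.tsv
# INFO xrefforge: status distribution: A: 2, a: 0, b: 0, B: 1
cat demo/status.tsv
# #reaction   status  min_flux  max_flux  regime
# EX_hub_in   A       0         1000      ORIGINAL
# EX_hub_out  A       0         1000      ORIGINAL
# R_dead0     B       0         0         ALL_RELAXED
```

The two hub exchanges can carry flux as written; the dead-end reaction stays
at zero even with every bound relaxed, so its blockage is topological.

Mapping any SBML model onto a namespace produces a mapped model plus a
diagnostic report:

```bash
xref-forge map --model model.xml --namespace demo/ns \
               --out mapped.xml --report report.tsv
```

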