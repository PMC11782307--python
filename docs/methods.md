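# Methods

This note records the model behind `glycoextract`, the parameters that
matter, and the design choices made where the rules left genuine freedom.

## Scope and preprocessing

The pipeline operates on molecular graphs; coordinates, isotopes, formal
charges and stereochemistry are carried through I/O but ignored by every
classification rule.  Screening removes only molecules containing
free-radical atoms and empty records.  Salts and other multi-component
records are kept: each connected component is analysed independently, and
a counter-ion simply yields no backbone.  Exotic elements are deliberately
*not* screened — a trimethylsilyl ether, for instance, is handled later as
a non-organic (hence non-glycan) modification, which localises the damage
to the modification instead of discarding the whole record.

Aromaticity uses RDKit's default model.  A "π-cyclic" atom is an aromatic
atom or a member of an SSSR ring whose atoms are all sp²/sp (this covers
quinone-like rings that the aromaticity model rejects).  A partially
saturated heterocycle such as a pyranose, a lactone or the enone ring of
levoglucosenone is *not* π-cyclic; this matters, because levoglucosenone
must be rejected by its modification count, not by ring perception.  A
"carbocycle" is an SSSR ring composed only of carbons, aromatic or not
(cyclitols, sterols).

## Backbone candidacy

Chain-eligible carbons exclude those in or directly bonded (one bond) to a
carbocycle or π-cyclic atom.  Carbon groups are the connected components
of the remaining C–C graph.  Candidacy conditions, with defaults:

| condition | default |
|---|---|
| carbons per group, branch carbons included (n_c) | 5–12 |
| branches (sum over carbons of max(0, C-degree − 2)) | ≤ 1 |
| in/adjacent to carbocycle or π-cyclic atom | not allowed |
| chain carbon in 3-/4-membered cyclic ether (one O, rest C) | not allowed |
| modification count | N_mod ≤ θ(n_c) |

The branch measure counts *excess degree*, so one quaternary carbon
carrying two extra arms counts two branches and is rejected, while a
single three-connected carbon (apiose-like skeletons) passes.

Chains are the maximal simple paths of the group's C–C graph; the
endocyclic C–O–C of sugar rings is never a path edge, so pyranoses and
furanoses are traversed open-chain and the ring oxygen becomes an anomeric
feature.  Path enumeration is exhaustive; groups are at most 12 carbons
with at most one branch, so the candidate count is tiny.

An **anomeric carbon** is a chain carbon with two or more single-bonded
O/N/S substituents of which at least one closes an SSSR ring back to the
chain (hemiacetal, hemiketal, and full acetals — glycosides keep their
anomeric character).  A **potential anomeric** carbonyl is a plain
aldehyde/ketone C=O; carboxyl-, ester- and amide-type carbonyls never
qualify.  The designated centre is chosen to minimise N_mod: a centre at
locant 1 or 2 is preferred (no penalty), then the lowest locant.  Chains
are numbered from the end that gives the designated centre the lower
locant; chains without one are oriented by the lowest canonical atom-rank
sequence, which makes all downstream output order-independent.

## Modification count

Reference state per carbon: the designated (potential) anomeric carbonyl
at position 1 or 2, one hydroxyl everywhere else.  Scores (all
configurable in the YAML config, defaults shown):

* deoxy carbon — saturated, no O/N/S substituent: **+1**
* each N-, S-, halogen- or other hetero-linked substituent: **+1**
* each oxygen substituent beyond the allowance (1; 2 at a ring-anomeric
  centre): **+1**
* terminal carboxyl or ester carbon: **+1** (semi-standard: sugar acids
  such as uronic, aldonic and aldaric acids stay monosaccharide-like)
* amide carbon: **+2** (a peptide bond raises a carboxyl from +1 to +2,
  which is what excludes peptide chains)
* carbon branch on the main chain: **+1** at the bearing carbon; the
  branch atoms are scored with the same substituent rules and the branch
  moiety itself becomes a modification
* C=C between consecutive main-chain carbons **+1**, C≡C **+2**,
  attributed to the lower locant
* each anhydro/lactone SSSR ring made of chain carbons and oxygens,
  beyond the single ring of the designated anomeric centre: **+1**
* each aldehyde/ketone carbonyl beyond the designated one: counted in
  `N_extra_carbonyl`, weighted ×2 in the total
* anomer penalty **+1** when the designated centre sits above locant 2 or
  when there is none at all (alditols); the two cases never stack.

Threshold: θ(n_c) = min(n_c − offset, cap), offset 3, cap 5; rejection is
strict (N_mod > θ), so a nonulosonate scoring exactly 5 is still a sugar.
Worked anchors used as regression values: glucose/fructose 0; glucitol 1
(no anomer); 5,7-diamino-3,5,7,9-tetradeoxy-non-2-ulosonic acid 5 (three
deoxy/amino pairs beyond Kdn's 2 plus the carboxyl); ascorbic acid 4 — the
lactone contributes +3 (missing anomeric centre, ring, carboxyl-like
carbon) and the ene-diol +1, exceeding θ(6) = 3; levoglucosenone 4
(anhydro ring, extra ketone ×2, ene); glutamic acid 6.

Main-chain selection: anomeric > potential anomeric > none, then longer
chain, then lower N_mod, lower modification locants, and finally the
canonical-rank sequence — a total order, so selection is deterministic and
input-order independent.

## Modifications and excision

Non-backbone atoms partition into connected modifications; each records
its attachment locants.  Classification:

1. every attachment at an anomeric carbon → **non-glycan** (aglycone).
   This applies whether the modification hangs off one backbone or spans
   several: a flavonoid bound through the anomeric oxygens of two glucoses
   is still an aglycone.  A group attached to an anomeric position of one
   residue and a non-anomeric position of another (an ordinary glycosidic
   oxygen) is a linkage and is kept.
2. contains a non-organic element → non-glycan.  Organic set:
   {C, H, N, O, P, S, F, Cl, Br, I}; phosphate and sulfate substituents
   must survive, silicon/boron/selenium/metals must not.
3. ≥ 5 atoms with three or more heavy-atom neighbours → non-glycan
   (complex branched groups).
4. contains an SSSR ring of ≥ 10 atoms entirely within the modification →
   non-glycan (macrolides).

Otherwise a modification is a linkage (≥ 2 backbones) or substituent.

Excision removes the non-glycan atoms except those directly bonded to a
backbone carbon; each such connecting atom is replaced by an oxygen,
whatever element it was, keeping its backbone bonds.  Consequences worth
noting: excising a methyl glycoside's methyl leaves the glycosidic oxygen
as a hydroxyl; a free anomeric hydroxyl "excises" to itself (the pipeline
is idempotent on its own output); and a single oxygen bridging two
anomeric centres (trehalose, sucrose) survives intact because the bridge
*is* the connecting atom.  With `--with-aglycone` the non-glycan groups
stay in place and are only labelled.

Fragments are the connected components containing at least one backbone,
reported largest-first then by canonical SMILES.

The Discussion-stage idea of excluding carbon chains that carry a long
hydrocarbon substituent anywhere but the anomeric carbon is exposed as the
config flag `forbid_long_acyl_on_non_anomeric` and is **off** by default:
acylated sugar backbones (saccharolipids such as Kdo2-lipid A) extract as
monosaccharide residues with their acyl and phosphate substituents
retained.  One boundary case follows directly from rule 1: a glycosyl
1-phosphate attaches only to the anomeric carbon and is excised like any
other aglycone.

## Fixture library

The fixture sets define the conditions every rule is tested under: the 23
constitutionally distinct skeletons covering the SNFG monosaccharide
symbols (stereoisomers collapsed; from hexose through muramic acid,
apiose, heptose, Kdo, Dha and the nonulosonates), the 20 proteinogenic
amino acids, five canonical nucleoside 5′-monophosphates, thirteen
lipid-database sugar acids/alcohols, worked borderline examples and
negative controls.  SMILES were transcribed from systematic names without
stereochemistry.  `mutate_stereo` decorates a fixture with a seeded,
reproducible stereoisomer for stereo-invariance property tests.

What the fixtures do not emulate: database-scale diversity (tautomers
drawn unusually, charged forms, organometallics beyond the TMS control),
so passing tests demonstrate rule correctness on the named chemistry, not
recall/precision on a full structure database.  The full-database numbers
in the literature depend on a LIPID MAPS snapshot and are out of scope.

## Numerical and degenerate-input choices

* All decisions are integer comparisons; there are no tolerances.
* Unparsable records are collected as per-record errors; a batch never
  aborts.  Empty input yields an empty report with exit 0.
* Oversized (n_c > 12) or over-branched groups skip chain enumeration —
  their verdict is already decided — which keeps lipid chains cheap.
* Determinism: canonical atom ranks break every tie (chain orientation,
  candidate selection, fragment and modification ordering); reports are
  byte-identical across runs and fragment SMILES are invariant under
  input atom permutation.

## Known limitations

* C-glycosides are not recognised: the glycosidic carbon reads as part of
  a carbon chain, and most natural C-glycosides are excluded anyway via
  their aromatic attachment.
* Part-of-chain sugars are not recognised: a backbone is always a whole
  maximal carbon group, so a monosaccharide fused into a longer chain
  (e.g. a macrolide backbone) is deliberately not cut out.
* The per-feature scoring table reproduces the published worked examples,
  but scoring of chemistry outside those anchors (e.g. gem-diols,
  thiocarbonyls) follows this package's generalisation of the rules; the
  YAML config is the adjustment point.
* Whole-structure classification is constitutional only; it never judges
  whether a sugar-like structure is biologically a sugar.
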