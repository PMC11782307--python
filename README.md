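# glycoextract

Extraction of glycan moieties from arbitrary small-molecule structures.

Chemical compound databases contain many glycosides, glycolipids and other
glycoconjugates, but their atom/bond representations do not say which atoms
form the sugar. `glycoextract` answers that question: given a structure in
SMILES, MOL or SDF form, it finds the monosaccharide backbone carbon
chains, decides which attached groups are glycan substituents or
inter-residue linkages and which are non-glycan aglycones, excises the
non-glycan parts with oxygen capping, and emits the glycan fragments as
canonical SMILES (or MOL/SDF) together with a JSON report of every
decision.

## The method

A candidate monosaccharide backbone is a *carbon group*: a maximal
connected set of carbons that are not in or next to a carbocycle, not in or
next to an aromatic/π-cyclic ring, with 5–12 carbons and at most one
branch, and no chain carbon in an epoxide/oxetane.  Every maximal linear
path through the group is scored by a **modification count** that measures
the distance from the basic monosaccharide state (one (potential) carbonyl
at position 1 or 2, one hydroxyl on every other carbon — an aldose or
2-ketose):

```
N_mod = Σ_i (N_replacement^i + N_unsaturation^i)
        + N_ring + 2·N_extra_carbonyl + N_anomer_penalty
```

Deoxy carbons, amino/thio/halo replacements, carboxyls (+1) and amides
(+2), chain unsaturation, anhydro/lactone rings, surplus carbonyls and a
missing or misplaced anomeric centre all add to `N_mod`.  A chain survives
when

```
N_mod ≤ θ(n_c) = min(n_c − 3, 5)
```

with `n_c` the carbon count of the group.  Among surviving chains the main
chain is chosen by priority: cyclic hemiacetal/hemiketal (anomeric) >
open-chain carbonyl (potential anomeric) > none, then longer chain, then a
deterministic tie-break.

Remaining atoms are partitioned into modifications.  A modification is
excised as non-glycan when it connects only to anomeric carbons (the
aglycone of a glycoside), contains a non-organic element, has ≥ 5
branches, or contains a ≥ 10-membered SSSR ring (macrolides).  Excised
groups are cut at the atom touching the backbone, which is replaced by an
oxygen — so an excised aglycone leaves an anomeric hydroxyl behind.

The rules are purely constitutional: stereochemistry never changes a
verdict, and stereoisomeric monosaccharides are treated as one structure.

## Worked example

```
$ cat demo.smi
OCC1OC(Oc2cc3c(OC4OC(COC(=O)C=Cc5ccc(O)cc5)C(O)C(O)C4O)cc(O)cc3[o+]c2-c2ccc(O)c(O)c2)C(O)C(O)C1O cyanidin-3-glc-5-(6-coumaroyl-glc)
NC(Cc1ccccc1)C(=O)O phenylalanine
$ glycoextract --in demo.smi --report demo.json
O=C(C=Cc1ccc(O)cc1)OCC1OC(O)C(O)C(O)C1O
OCC1OC(O)C(O)C(O)C1O
```

The flavonoid diglucoside yields two fragments: 6-*p*-coumaroylglucose and
glucose.  The cyanidin core is attached through the anomeric oxygens of
both glucoses only, so it is excised as an aglycone (each glycosidic
oxygen stays behind as a hydroxyl cap), while the coumaroyl ester sits at
the non-anomeric O-6 and is kept as a substituent.  Phenylalanine yields
nothing.  The report records the reasons:

```
records 2   with glycan 1   fragments 2
cyanidin-3-glc-5-(6-coumaroyl-glc): each glucose group has n_c = 6,
    N_mod = 0 ≤ θ(6) = 3, passed
phenylalanine: rejection_category = aromatic_or_pi_cyclic
```

The same pipeline is available as a library:

```python
from glycoextract import MolecularGraph, extract_glycans
frags = extract_glycans(MolecularGraph.from_smiles("COC1OC(CO)C(O)C(O)C1O"))
print([f.smiles for f in frags])   # ['OCC1OC(O)C(O)C(O)C1O']
```

A bundled fixture library (`glycoextract.fixtures`) carries the named
validation structures — the 23 SNFG monosaccharide skeletons, the 20
proteinogenic amino acids, canonical nucleotides, thirteen
sugar-acid/alcohol lipid-database entries and worked examples such as
ascorbic acid, levoglucosenone and Kdo2-lipid A — each with its expected
classification.

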