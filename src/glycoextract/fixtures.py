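"""Named test structures with expected classifications.

Every structure the rule set was validated against is available here as a
stereochemistry-free SMILES together with its expected behaviour, so the
whole rule set is testable without any external download.  SMILES were
transcribed from the systematic names of the structures; stereochemistry
is omitted throughout because classification is purely constitutional.

Sets
----
``snfg_monosaccharides``
    The 23 constitutionally distinct skeletons covering the SNFG
    monosaccharide symbols (stereoisomers collapsed); all must be accepted.
``amino_acids_20``
    The 20 proteinogenic amino acids; none contains a glycan.
``nucleotides``
    Canonical nucleoside 5'-monophosphates; none contains a glycan.
``fig5_lipids``
    Thirteen LIPID-MAPS fatty-acyl entries (sugar acids/alcohols) whose
    whole structure classifies as sugar.
``worked_examples``
    Borderline and pipeline demonstration structures (ascorbic acid,
    levoglucosenone, glycosides, a flavonoid diglucoside, Kdo2-lipid A...).
``negative_controls``
    Structures that must never yield a glycan.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from rdkit import Chem
from rdkit.Chem.EnumerateStereoisomers import (
    EnumerateStereoisomers,
    StereoEnumerationOptions,
)


@dataclass(frozen=True)
class FixtureEntry:
    id: str
    smiles: str
    is_monosaccharide: Optional[bool] = None  # whole structure is one sugar unit
    expected_n_mod: Optional[int] = None
    expected_fragments: Optional[int] = None
    expected_rejection: Optional[str] = None
    provenance: str = ""


def _e(id, smiles, **kw) -> FixtureEntry:
    return FixtureEntry(id=id, smiles=smiles, **kw)


# -- acyl-chain shorthand for the saccharolipid fixture ---------------------
_OH_C14 = "C(=O)CC(O)CCCCCCCCCCC"  # 3-hydroxymyristoyl
_LAURYL_OXO_C14 = "C(=O)CC(OC(=O)CCCCCCCCCCC)CCCCCCCCCCC"  # 3-O-lauroyl-myristoyl
_MYRISTYL_OXO_C14 = "C(=O)CC(OC(=O)CCCCCCCCCCCCC)CCCCCCCCCCC"  # 3-O-myristoyl-myristoyl

#: hexa-acylated glucosamine disaccharide bisphosphate carrying two Kdo
#: residues -- the minimal E. coli lipopolysaccharide
KDO2_LIPID_A = (
    "OP(=O)(O)OC1OC(COC2OC(COC3(C(=O)O)CC(OC4(C(=O)O)CC(O)C(O)C(C(O)CO)O4)"
    "C(O)C(C(O)CO)O3)C(OP(=O)(O)O)C(O" + _MYRISTYL_OXO_C14 + ")C2N"
    + _LAURYL_OXO_C14 + ")C(O)C(O" + _OH_C14 + ")C1N" + _OH_C14
)

_SETS: dict[str, list[FixtureEntry]] = {}

_SETS["snfg_monosaccharides"] = [
    _e("hexose", "OCC1OC(O)C(O)C(O)C1O", expected_n_mod=0),
    _e("hexnac", "CC(=O)NC1C(O)OC(CO)C(O)C1O", expected_n_mod=1),
    _e("hexosamine", "NC1C(O)OC(CO)C(O)C1O", expected_n_mod=1),
    _e("hexuronate", "OC(=O)C1OC(O)C(O)C(O)C1O", expected_n_mod=1),
    _e("deoxyhexose", "CC1OC(O)C(O)C(O)C1O", expected_n_mod=1),
    _e("deoxyhexnac", "CC1OC(O)C(NC(C)=O)C(O)C1O", expected_n_mod=2),
    _e("dideoxyhexose_2_6", "CC1OC(O)CC(O)C1O", expected_n_mod=2),
    _e("dideoxyhexose_3_6", "CC1OC(O)C(O)CC1O", expected_n_mod=2),
    _e("pentose", "OCC1OC(O)C(O)C1O", expected_n_mod=0),
    _e("kdn", "OC(=O)C1(O)CC(O)C(O)C(O1)C(O)C(O)CO", expected_n_mod=2),
    _e("neuraminic_acid", "OC(=O)C1(O)CC(O)C(N)C(O1)C(O)C(O)CO",
       expected_n_mod=3),
    _e("neu5ac", "OC(=O)C1(O)CC(O)C(NC(C)=O)C(O1)C(O)C(O)CO",
       expected_n_mod=3),
    _e("neu5gc", "OC(=O)C1(O)CC(O)C(NC(=O)CO)C(O1)C(O)C(O)CO",
       expected_n_mod=3),
    # 5,7-diamino-3,5,7,9-tetradeoxy-non-2-ulosonic acid: the shared
    # skeleton of Pse/Leg/Aci/4eLeg, the most modified SNFG sugar
    _e("diamino_tetradeoxy_nonulosonic", "OC(=O)C1(O)CC(O)C(N)C(O1)C(N)C(O)C",
       expected_n_mod=5),
    _e("bacillosamine", "CC1OC(O)C(N)C(O)C1N", expected_n_mod=3),
    _e("heptose", "OCC(O)C1OC(O)C(O)C(O)C1O", expected_n_mod=0),
    _e("kdo", "OC(=O)C1(O)CC(O)C(O)C(O1)C(O)CO", expected_n_mod=2),
    _e("dha", "OC(=O)C(=O)CC(O)C(O)C(O)C(=O)O", expected_n_mod=3),
    _e("muramic_acid", "OCC1OC(O)C(N)C(OC(C)C(=O)O)C1O", expected_n_mod=1),
    _e("murnac", "OCC1OC(O)C(NC(C)=O)C(OC(C)C(=O)O)C1O", expected_n_mod=1),
    _e("murngc", "OCC1OC(O)C(NC(=O)CO)C(OC(C)C(=O)O)C1O", expected_n_mod=1),
    _e("apiose", "OCC(O)(CO)C(O)C=O", expected_n_mod=1),
    _e("hexulose", "OCC(=O)C(O)C(O)C(O)CO", expected_n_mod=0),
]
_SETS["snfg_monosaccharides"] = [
    replace(e, is_monosaccharide=True, expected_fragments=1,
            provenance="SNFG skeleton, stereo-collapsed")
    for e in _SETS["snfg_monosaccharides"]
]

_SETS["amino_acids_20"] = [
    _e("Gly", "NCC(=O)O", expected_rejection="chain_too_short"),
    _e("Ala", "CC(N)C(=O)O", expected_rejection="chain_too_short"),
    _e("Ser", "OCC(N)C(=O)O", expected_rejection="chain_too_short"),
    _e("Cys", "SCC(N)C(=O)O", expected_rejection="chain_too_short"),
    _e("Thr", "CC(O)C(N)C(=O)O", expected_rejection="chain_too_short"),
    _e("Asp", "OC(=O)CC(N)C(=O)O", expected_rejection="chain_too_short"),
    _e("Asn", "NC(=O)CC(N)C(=O)O", expected_rejection="chain_too_short"),
    _e("Met", "CSCCC(N)C(=O)O", expected_rejection="chain_too_short"),
    _e("Phe", "NC(Cc1ccccc1)C(=O)O",
       expected_rejection="aromatic_or_pi_cyclic"),
    _e("Tyr", "NC(Cc1ccc(O)cc1)C(=O)O",
       expected_rejection="aromatic_or_pi_cyclic"),
    _e("Trp", "NC(Cc1c[nH]c2ccccc12)C(=O)O",
       expected_rejection="aromatic_or_pi_cyclic"),
    _e("His", "NC(Cc1c[nH]cn1)C(=O)O",
       expected_rejection="aromatic_or_pi_cyclic"),
    _e("Glu", "OC(=O)CCC(N)C(=O)O",
       expected_rejection="modification_count_exceeded"),
    _e("Gln", "NC(=O)CCC(N)C(=O)O",
       expected_rejection="modification_count_exceeded"),
    _e("Arg", "NC(=N)NCCCC(N)C(=O)O",
       expected_rejection="modification_count_exceeded"),
    _e("Lys", "NCCCCC(N)C(=O)O",
       expected_rejection="modification_count_exceeded"),
    _e("Pro", "OC(=O)C1CCCN1",
       expected_rejection="modification_count_exceeded"),
    _e("Val", "CC(C)C(N)C(=O)O",
       expected_rejection="modification_count_exceeded"),
    _e("Leu", "CC(C)CC(N)C(=O)O",
       expected_rejection="modification_count_exceeded"),
    _e("Ile", "CCC(C)C(N)C(=O)O",
       expected_rejection="modification_count_exceeded"),
]
_SETS["amino_acids_20"] = [
    replace(e, expected_fragments=0, provenance="proteinogenic amino acid")
    for e in _SETS["amino_acids_20"]
]

_SETS["nucleotides"] = [
    replace(e, expected_fragments=0,
            expected_rejection="aromatic_or_pi_cyclic",
            provenance="canonical nucleoside 5'-monophosphate")
    for e in [
        _e("AMP", "Nc1ncnc2c1ncn2C1OC(COP(=O)(O)O)C(O)C1O"),
        _e("GMP", "Nc1nc2c(ncn2C2OC(COP(=O)(O)O)C(O)C2O)c(=O)[nH]1"),
        _e("CMP", "Nc1ccn(C2OC(COP(=O)(O)O)C(O)C2O)c(=O)n1"),
        _e("UMP", "O=c1ccn(C2OC(COP(=O)(O)O)C(O)C2O)c(=O)[nH]1"),
        _e("dTMP", "Cc1cn(C2CC(O)C(COP(=O)(O)O)O2)c(=O)[nH]1"),
    ]
]

_SETS["fig5_lipids"] = [
    replace(e, is_monosaccharide=True,
            provenance="LIPID MAPS fatty-acyl entry wholly classified as sugar")
    for e in [
        _e("LMFA01050471_2_5_didehydro_gluconic_acid",
           "OC(=O)C(=O)C(O)C(O)C(=O)CO", expected_n_mod=3,
           expected_fragments=1),
        _e("LMFA01050473_2_amino_2_3_7_trideoxy_hept_6_ulosonic_acid",
           "OC(=O)C(N)CC(O)C(O)C(=O)C", expected_n_mod=4,
           expected_fragments=1),
        _e("LMFA01050474_2_dehydro_3_deoxy_arabinonic_acid",
           "OC(=O)C(=O)CC(O)CO", expected_n_mod=2, expected_fragments=1),
        _e("LMFA01050475_2_dehydro_3_deoxy_gluconic_acid",
           "OC(=O)C(=O)CC(O)C(O)CO", expected_n_mod=2, expected_fragments=1),
        _e("LMFA01050476_2_dehydro_3_deoxy_l_arabinonic_acid",
           "OC(=O)C(=O)CC(O)CO", expected_n_mod=2, expected_fragments=1),
        _e("LMFA01050486_2_keto_3_deoxy_gluconic_acid",
           "OC(=O)C(=O)CC(O)C(O)CO", expected_n_mod=2, expected_fragments=1),
        _e("LMFA01050532_fuconic_acid",
           "CC(O)C(O)C(O)C(O)C(=O)O", expected_n_mod=3, expected_fragments=1),
        _e("LMFA01060195_diketo_gulonic_acid",
           "OC(=O)C(=O)C(=O)C(O)C(O)CO", expected_n_mod=3,
           expected_fragments=1),
        _e("LMFA01170107_galactaric_acid",
           "OC(=O)C(O)C(O)C(O)C(O)C(=O)O", expected_n_mod=3,
           expected_fragments=1),
        _e("LMFA01170108_glucaric_acid",
           "OC(=O)C(O)C(O)C(O)C(O)C(=O)O", expected_n_mod=3,
           expected_fragments=1),
        _e("LMFA05000598_1_deoxy_glucitol",
           "CC(O)C(O)C(O)C(O)CO", expected_n_mod=2, expected_fragments=1),
        _e("LMFA05000654_tagaturonic_acid",
           "OCC(=O)C(O)C(O)C(O)C(=O)O", expected_n_mod=1,
           expected_fragments=1),
        _e("LMFA13010063_hexopyranosyl_hexitol",
           "OCC1OC(OCC(O)C(O)C(O)C(O)CO)C(O)C(O)C1O",
           expected_fragments=1),
    ]
]

_SETS["worked_examples"] = [
    _e("glucose", "OCC1OC(O)C(O)C(O)C1O", is_monosaccharide=True,
       expected_n_mod=0, expected_fragments=1),
    _e("open_chain_glucose", "OCC(O)C(O)C(O)C(O)C=O", is_monosaccharide=True,
       expected_n_mod=0, expected_fragments=1),
    _e("fructose", "OCC(=O)C(O)C(O)C(O)CO", is_monosaccharide=True,
       expected_n_mod=0, expected_fragments=1),
    _e("glucitol", "OCC(O)C(O)C(O)C(O)CO", is_monosaccharide=True,
       expected_n_mod=1, expected_fragments=1),
    _e("levoglucosan", "OC1C(O)C(O)C2COC1O2", is_monosaccharide=True,
       expected_n_mod=1, expected_fragments=1),
    _e("ascorbic_acid", "OCC(O)C1OC(=O)C(O)=C1O", is_monosaccharide=False,
       expected_n_mod=4, expected_fragments=0,
       expected_rejection="modification_count_exceeded"),
    _e("levoglucosenone", "O=C1C=CC2COC1O2", is_monosaccharide=False,
       expected_n_mod=4, expected_fragments=0,
       expected_rejection="modification_count_exceeded"),
    _e("isolevoglucosenone", "O=C1C=CC2OCC1O2", is_monosaccharide=False,
       expected_n_mod=4, expected_fragments=0,
       expected_rejection="modification_count_exceeded"),
    _e("forosamine", "CC1OC(O)CCC1N(C)C", is_monosaccharide=False,
       expected_n_mod=4, expected_fragments=0,
       expected_rejection="modification_count_exceeded"),
    _e("purpurosamine_c", "OC1OC(CN)CCC1N", is_monosaccharide=False,
       expected_n_mod=4, expected_fragments=0,
       expected_rejection="modification_count_exceeded"),
    _e("kdn", "OC(=O)C1(O)CC(O)C(O)C(O1)C(O)C(O)CO", is_monosaccharide=True,
       expected_n_mod=2, expected_fragments=1),
    _e("neuraminic_acid", "OC(=O)C1(O)CC(O)C(N)C(O1)C(O)C(O)CO",
       is_monosaccharide=True, expected_n_mod=3, expected_fragments=1),
    _e("diamino_tetradeoxy_nonulosonic",
       "OC(=O)C1(O)CC(O)C(N)C(O1)C(N)C(O)C", is_monosaccharide=True,
       expected_n_mod=5, expected_fragments=1),
    _e("methyl_glucoside", "COC1OC(CO)C(O)C(O)C1O", expected_fragments=1),
    _e("lactose", "OCC1OC(OC2C(O)C(O)C(CO)OC2O)C(O)C(O)C1O",
       expected_fragments=1),
    _e("cyanidin_3_glucoside_5_coumaroylglucoside",
       "OCC1OC(Oc2cc3c(OC4OC(COC(=O)C=Cc5ccc(O)cc5)C(O)C(O)C4O)cc(O)cc3"
       "[o+]c2-c2ccc(O)c(O)c2)C(O)C(O)C1O",
       expected_fragments=2),
    _e("trimethylsilyl_glucoside", "C[Si](C)(C)OC1OC(CO)C(O)C(O)C1O",
       expected_fragments=1),
    _e("glutamic_acid", "OC(=O)CCC(N)C(=O)O", expected_fragments=0,
       expected_n_mod=6,
       expected_rejection="modification_count_exceeded"),
    _e("glutamylalanine", "OC(=O)C(N)CCC(=O)NC(C)C(=O)O",
       expected_fragments=0, expected_n_mod=7,
       expected_rejection="modification_count_exceeded"),
    _e("kdo2_lipid_a", KDO2_LIPID_A, expected_fragments=1),
]
_SETS["worked_examples"] = [
    replace(e, provenance=e.provenance or "worked example")
    for e in _SETS["worked_examples"]
]

_SETS["negative_controls"] = [
    replace(e, expected_fragments=0, provenance="negative control")
    for e in [
        _e("octane", "CCCCCCCC",
           expected_rejection="modification_count_exceeded"),
        _e("benzene", "c1ccccc1",
           expected_rejection="aromatic_or_pi_cyclic"),
        _e("glyceraldehyde", "OCC(O)C=O",
           expected_rejection="chain_too_short"),
        _e("erythrose", "OCC(O)C(O)C=O",
           expected_rejection="chain_too_short"),
        _e("myo_inositol", "OC1C(O)C(O)C(O)C(O)C1O",
           expected_rejection="carbocycle"),
        _e("cholesterol", "CC(CCCC(C)C)C1CCC2C1(C)CCC1C2CCC2=CC(O)CCC12C",
           expected_rejection="modification_count_exceeded"),
        _e("anhydro_epoxy_hexose", "OCC1OC(O)C2OC12",
           expected_rejection="structure_rules"),
        _e("pentaerythritol", "OCC(CO)(CO)CO",
           expected_rejection="structure_rules"),
    ]
]

SET_NAMES = tuple(_SETS)


def fixture_set(name: str) -> list[FixtureEntry]:
    """Return one of the named fixture sets (a fresh list)."""
    try:
        return list(_SETS[name])
    except KeyError:
        raise ValueError(
            f"unknown fixture set {name!r}; available: {sorted(_SETS)}"
        ) from None


def all_fixtures() -> list[FixtureEntry]:
    return [e for name in SET_NAMES for e in _SETS[name]]


def mutate_stereo(entry: FixtureEntry, seed: int) -> FixtureEntry:
    """A stereo-decorated variant of a fixture, same expected classification.

    Deterministic for a given seed; entries without stereocenters are
    returned unchanged.  Used by stereo-invariance property tests: the
    classification rules never look at stereochemistry.
    """
    mol = Chem.MolFromSmiles(entry.smiles)
    opts = StereoEnumerationOptions(maxIsomers=16, onlyUnassigned=True)
    isomers = sorted(
        Chem.MolToSmiles(m) for m in EnumerateStereoisomers(mol, opts)
    )
    if len(isomers) <= 1:
        return entry
    pick = isomers[seed % len(isomers)]
    return replace(entry, smiles=pick)


def write_fixture_files(sdf_path, json_path) -> None:
    """Export all fixtures as an SDF plus a JSON expectations file."""
    import json
    from dataclasses import asdict

    from .molio import write_fragment

    entries = []
    with open(sdf_path, "w") as sdf:
        for name in SET_NAMES:
            for e in _SETS[name]:
                mol = Chem.MolFromSmiles(e.smiles)
                mol.SetProp("_Name", e.id)
                sdf.write(write_fragment(mol, "sdf"))
                entries.append({"set": name, **asdict(e)})
    with open(json_path, "w") as fh:
        json.dump(entries, fh, indent=1)
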