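"""Modification classification, aglycone excision and fragment assembly."""

import random

import pytest
from rdkit.Chem import rdmolops

from glycoextract import (
    ExtractionOptions,
    MolecularGraph,
    analyze,
    extract_glycans,
)
from glycoextract.extract import LINKAGE, NON_GLYCAN, SUBSTITUENT
from glycoextract.fixtures import KDO2_LIPID_A

GLUCOPYRANOSE = "OCC1OC(O)C(O)C(O)C1O"
LACTOSE = "OCC1OC(OC2C(O)C(O)C(CO)OC2O)C(O)C(O)C1O"
CYANIDIN_DIGLUCOSIDE = (
    "OCC1OC(Oc2cc3c(OC4OC(COC(=O)C=Cc5ccc(O)cc5)C(O)C(O)C4O)cc(O)cc3"
    "[o+]c2-c2ccc(O)c(O)c2)C(O)C(O)C1O"
)


def graph(smi):
    return MolecularGraph.from_smiles(smi)


class TestModificationPartition:
    def test_glucopyranose_hydroxyls_and_ring_oxygen(self):
        a = analyze(graph(GLUCOPYRANOSE))
        assert len(a.modifications) == 6  # 5 hydroxyls + endocyclic oxygen
        ring_o = [m for m in a.modifications if len(m.attachments) == 2]
        assert len(ring_o) == 1
        assert sorted(att.locant for att in ring_o[0].attachments) == [1, 5]

    def test_lactose_bridging_oxygen_is_linkage(self):
        a = analyze(graph(LACTOSE))
        bridges = [
            m
            for m in a.modifications
            if len({att.backbone_index for att in m.attachments}) == 2
        ]
        assert len(bridges) == 1
        assert bridges[0].mclass == LINKAGE
        assert len(a.fragments) == 1
        assert len(a.fragments[0].backbones) == 2

    def test_methyl_glucoside_anomeric_only_rule(self):
        a = analyze(graph("COC1OC(CO)C(O)C(O)C1O"))
        methyl = [m for m in a.modifications if "C" in m.features.elements]
        assert methyl and methyl[0].features.anomeric_only
        assert methyl[0].mclass == NON_GLYCAN
        (frag,) = a.fragments
        assert frag.smiles == "OCC1OC(O)C(O)C(O)C1O"  # capped to glucose
        assert frag.excision_caps

    def test_non_organic_modification_excised(self):
        a = analyze(graph("C[Si](C)(C)OC1OC(CO)C(O)C(O)C1O"))
        assert any(
            m.mclass == NON_GLYCAN and m.features.has_non_organic()
            for m in a.modifications
        )
        assert a.fragments[0].smiles == "OCC1OC(O)C(O)C(O)C1O"

    def test_macrocycle_modification_excised(self):
        # cyclododecyl ether at a non-anomeric position: 12-membered SSSR
        smi = "OCC1OC(O)C(O)C(O)C1OC1CCCCCCCCCCC1"
        a = analyze(graph(smi))
        macro = [m for m in a.modifications if m.features.max_sssr_ring_size]
        assert macro and macro[0].features.max_sssr_ring_size == 12
        assert macro[0].mclass == NON_GLYCAN
        assert a.fragments[0].smiles == GLUCOPYRANOSE

    def test_branchy_modification_excised(self):
        dendron = "OC(C(C)(C)C)(C(C)(C)C)C(C)(C)C(C)(C)C"
        smi = "OCC1OC(O)C(O)C(O)C1" + dendron
        a = analyze(graph(smi))
        big = max(a.modifications, key=lambda m: len(m.atom_indices))
        assert big.features.branch_count >= 5
        assert big.mclass == NON_GLYCAN

    def test_coumaroyl_substituent_below_thresholds(self):
        a = analyze(graph(CYANIDIN_DIGLUCOSIDE))
        coumaroyl = [
            m
            for m in a.modifications
            if m.mclass == SUBSTITUENT and "C" in m.features.elements
            and m.features.max_sssr_ring_size == 6
        ]
        assert coumaroyl and coumaroyl[0].features.branch_count < 5


class TestExcision:
    def test_flavonoid_diglucoside_two_fragments(self):
        frags = extract_glycans(graph(CYANIDIN_DIGLUCOSIDE))
        assert len(frags) == 2
        smiles = sorted(f.smiles for f in frags)
        assert "OCC1OC(O)C(O)C(O)C1O" in smiles  # plain glucose
        # the other keeps the coumaroyl ester on C6
        other = next(s for s in smiles if s != "OCC1OC(O)C(O)C(O)C1O")
        assert "C=C" in other and "c1" in other

    def test_free_glucose_unchanged(self):
        (frag,) = extract_glycans(graph(GLUCOPYRANOSE))
        assert frag.smiles == GLUCOPYRANOSE

    def test_octane_and_amino_acids_yield_nothing(self):
        assert extract_glycans(graph("CCCCCCCC")) == []
        assert extract_glycans(graph("NC(Cc1ccccc1)C(=O)O")) == []

    def test_with_aglycone_retains_superset(self):
        base = extract_glycans(graph(CYANIDIN_DIGLUCOSIDE))
        full = extract_glycans(
            graph(CYANIDIN_DIGLUCOSIDE), ExtractionOptions(with_aglycone=True)
        )
        base_atoms = set().union(*[f.parent_atoms for f in base])
        full_atoms = set().union(*[f.parent_atoms for f in full])
        assert base_atoms - {a for f in base for a in f.excision_caps} <= full_atoms
        assert len(full) == 1  # aglycone bridge keeps one connected piece
        assert full[0].aglycone_atoms

    def test_saccharolipid_backbones_extracted_with_acyls(self):
        a = analyze(graph(KDO2_LIPID_A))
        (frag,) = a.fragments
        assert len(frag.backbones) == 4
        assert sorted(bb.group.n_c for bb in frag.backbones) == [6, 6, 8, 8]
        # acyl chains and the non-anomeric phosphate stay as substituents
        assert "P" in frag.smiles
        assert any(
            m.mclass == SUBSTITUENT and "N" in m.features.elements
            for m in frag.modifications
        )


class TestStructuralInvariants:
    FIXTURE_IDS = [
        "glucose", "methyl_glucoside", "lactose", "trimethylsilyl_glucoside",
        "cyanidin_3_glucoside_5_coumaroylglucoside", "kdo2_lipid_a",
        "LMFA13010063_hexopyranosyl_hexitol",
    ]

    def test_atom_partition_is_exact(self, analyzed_fixtures):
        """Backbone atoms and modification atoms tile the molecule."""
        for fid in self.FIXTURE_IDS:
            entry, a = analyzed_fixtures[fid]
            if not a.fragments:
                continue
            backbone = {
                c
                for f in a.fragments
                for bb in f.backbones
                for c in bb.chain.ordered_carbons
            }
            mod_atoms = [i for m in a.modifications for i in m.atom_indices]
            assert len(mod_atoms) == len(set(mod_atoms))
            assert backbone | set(mod_atoms) == {
                at.index for at in a.graph.atoms
            }
            assert not backbone & set(mod_atoms)

    def test_atom_conservation_through_excision(self, analyzed_fixtures):
        """Kept atoms + excised atoms + caps account for every heavy atom."""
        for fid in self.FIXTURE_IDS:
            entry, a = analyzed_fixtures[fid]
            if not a.fragments:
                continue
            kept = set().union(*[f.parent_atoms for f in a.fragments])
            caps = {c for f in a.fragments for c in f.excision_caps}
            excised = set()
            for m in a.modifications:
                if m.mclass == NON_GLYCAN:
                    connecting = {att.connecting_atom for att in m.attachments}
                    excised |= m.atom_indices - connecting
            all_atoms = {at.index for at in a.graph.atoms}
            assert kept | excised == all_atoms
            assert not kept & excised
            assert caps <= kept

    def test_idempotent_on_emitted_fragments(self, analyzed_fixtures):
        for fid in self.FIXTURE_IDS:
            entry, a = analyzed_fixtures[fid]
            for frag in a.fragments:
                again = extract_glycans(frag.graph)
                assert len(again) == 1
                assert again[0].smiles == frag.smiles
                assert sorted(b.breakdown.n_mod for b in again[0].backbones) == sorted(
                    b.breakdown.n_mod for b in frag.backbones
                )

    @pytest.mark.parametrize(
        "smiles", [GLUCOPYRANOSE, LACTOSE, CYANIDIN_DIGLUCOSIDE]
    )
    def test_output_invariant_under_atom_permutation(self, smiles):
        g = graph(smiles)
        ref = sorted(f.smiles for f in extract_glycans(g))
        rng = random.Random(11)
        for _ in range(3):
            perm = list(range(g.num_heavy_atoms()))
            rng.shuffle(perm)
            g2 = MolecularGraph(rdmolops.RenumberAtoms(g.rdmol, perm))
            assert sorted(f.smiles for f in extract_glycans(g2)) == ref

    def test_options_validation(self):
        with pytest.raises(ValueError):
            ExtractionOptions(max_mod_branches=0)
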