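"""Carbon group perception, chain enumeration and main-chain selection."""

import random

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit.Chem import rdmolops

from glycoextract import MolecularGraph, find_carbon_groups
from glycoextract.chains import (
    ANOMER,
    NO_ANOMER,
    POTENTIAL_ANOMER,
    _maximal_simple_paths,
    detect_anomeric,
    enumerate_chains,
    select_main_chain,
)
from glycoextract.graph import induced_carbon_adjacency
from glycoextract.modcount import count_modifications

GLUCOPYRANOSE = "OCC1OC(O)C(O)C(O)C1O"


def graph(smi):
    return MolecularGraph.from_smiles(smi)


class TestFindCarbonGroups:
    def test_glucose_single_hexose_group(self):
        groups = find_carbon_groups(graph(GLUCOPYRANOSE))
        assert len(groups) == 1
        assert groups[0].n_c == 6
        assert groups[0].branch_count == 0

    def test_phenylalanine_truncated_by_aromatics(self):
        # the benzylic CH2 is adjacent to the aromatic ring and is removed,
        # leaving no group of candidate size
        groups = find_carbon_groups(graph("NC(Cc1ccccc1)C(=O)O"))
        assert all(g.n_c < 5 for g in groups)

    def test_inositol_carbocycle_excluded(self):
        assert find_carbon_groups(graph("OC1C(O)C(O)C(O)C(O)C1O")) == []

    def test_disaccharide_two_groups(self):
        lactose = "OCC1OC(OC2C(O)C(O)C(CO)OC2O)C(O)C(O)C1O"
        groups = find_carbon_groups(graph(lactose))
        assert [g.n_c for g in groups] == [6, 6]

    def test_invariant_under_atom_permutation(self):
        g = graph(GLUCOPYRANOSE)
        sizes = sorted(gr.n_c for gr in find_carbon_groups(g))
        rng = random.Random(7)
        for _ in range(5):
            perm = list(range(g.num_heavy_atoms()))
            rng.shuffle(perm)
            g2 = MolecularGraph(rdmolops.RenumberAtoms(g.rdmol, perm))
            assert sorted(gr.n_c for gr in find_carbon_groups(g2)) == sizes


def brute_force_maximal_paths(adj):
    """Independent path oracle: exhaustive simple-path enumeration."""
    G = nx.Graph()
    G.add_nodes_from(adj)
    G.add_edges_from((u, v) for u, vs in adj.items() for v in vs)
    found = set()
    nodes = sorted(G)
    for i, s in enumerate(nodes):
        for t in nodes[i:]:
            it = [[s]] if s == t else nx.all_simple_paths(G, s, t)
            for p in it:
                if any(n not in p for n in G[p[0]]):
                    continue
                if any(n not in p for n in G[p[-1]]):
                    continue
                tp = tuple(p)
                found.add(min(tp, tuple(reversed(tp))))
    return found


class TestChainEnumeration:
    @pytest.mark.parametrize(
        "smiles",
        [
            GLUCOPYRANOSE,
            "OCC(O)(CO)C(O)C=O",  # apiose: one branch point
            "CCC(C)C(N)C(=O)O",  # isoleucine skeleton
            "OCC(O)C(O)C(CO)C(O)CO",  # branched heptitol
            "CC(C)(C)CC(C)(C)C",  # dendritic: many maximal paths
        ],
    )
    def test_matches_brute_force_oracle(self, smiles):
        g = graph(smiles)
        carbons = g.carbon_indices()
        adj = induced_carbon_adjacency(g, carbons)
        assert set(_maximal_simple_paths(adj)) == brute_force_maximal_paths(adj)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle_on_random_trees(self, seed):
        rng = random.Random(seed)
        n = rng.randint(2, 10)
        G = nx.random_labeled_tree(n, seed=seed)
        adj = {v: sorted(G[v]) for v in G}
        assert set(_maximal_simple_paths(adj)) == brute_force_maximal_paths(adj)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=1, max_value=8),
        edge_bits=st.integers(min_value=0),
    )
    def test_matches_oracle_on_arbitrary_small_graphs(self, n, edge_bits):
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        adj = {i: [] for i in range(n)}
        for k, (i, j) in enumerate(pairs):
            if (edge_bits >> k) & 1:
                adj[i].append(j)
                adj[j].append(i)
        assert set(_maximal_simple_paths(adj)) == brute_force_maximal_paths(adj)

    def test_unbranched_group_single_path(self):
        g = graph(GLUCOPYRANOSE)
        (grp,) = find_carbon_groups(g)
        chains = enumerate_chains(grp, g)
        assert len(chains) == 1
        assert chains[0].length == 6
        assert chains[0].branch_carbons == frozenset()

    def test_branched_group_paths_cover_each_arm(self):
        g = graph("OCC(O)C(O)C(CO)C(O)CO")  # 7 carbons, one branch point
        (grp,) = find_carbon_groups(g)
        chains = enumerate_chains(grp, g)
        lengths = sorted(c.length for c in chains)
        assert lengths == [4, 5, 6]  # each pair of arms through the branch point
        for c in chains:
            assert len(c.all_carbons) == 7


class TestDetectAnomeric:
    @pytest.mark.parametrize(
        "smiles,status,position",
        [
            (GLUCOPYRANOSE, ANOMER, 1),  # cyclic hemiacetal
            ("OCC(=O)C(O)C(O)C(O)CO", POTENTIAL_ANOMER, 2),  # 2-ketose
            ("OCC(O)C(O)C(O)C(O)C=O", POTENTIAL_ANOMER, 1),  # open aldose
            ("OCC(O)C(O)C(O)C(O)CO", NO_ANOMER, None),  # alditol
            ("COC1OC(CO)C(O)C(O)C1O", ANOMER, 1),  # glycoside (acetal)
        ],
    )
    def test_status_and_position(self, smiles, status, position):
        g = graph(smiles)
        grp = max(find_carbon_groups(g), key=lambda x: x.n_c)
        (chain,) = enumerate_chains(grp, g)
        assert chain.anomeric_status == status
        assert chain.anomeric_position == position

    def test_carboxyl_is_not_a_potential_anomer(self):
        g = graph("OC(=O)C(O)C(O)C(O)C(O)C(=O)O")  # glucaric acid
        (grp,) = find_carbon_groups(g)
        (chain,) = enumerate_chains(grp, g)
        assert chain.anomeric_status == NO_ANOMER


class TestSelectMainChain:
    def _best(self, smiles):
        g = graph(smiles)
        (grp,) = find_carbon_groups(g)
        chains = enumerate_chains(grp, g)
        counts = {c: count_modifications(c, g) for c in chains}
        return g, chains, counts

    def test_single_candidate_identity(self):
        g, chains, counts = self._best(GLUCOPYRANOSE)
        assert select_main_chain(chains, g, counts) == chains[0]

    def test_longer_chain_preferred(self):
        g, chains, counts = self._best("OCC(O)C(O)C(CO)C(O)CO")
        best = select_main_chain(chains, g, counts)
        assert best.length == 6

    def test_potential_anomer_beats_plain_chain(self):
        # branched: the aldehyde-containing arm must win over equal length
        g, chains, counts = self._best("O=CC(O)C(O)C(CO)C(O)CO")
        best = select_main_chain(chains, g, counts)
        assert best.anomeric_status == POTENTIAL_ANOMER

    def test_invariant_to_input_order(self):
        g, chains, counts = self._best("OCC(O)C(O)C(CO)C(O)CO")
        rng = random.Random(3)
        ref = select_main_chain(chains, g, counts)
        for _ in range(5):
            shuffled = chains[:]
            rng.shuffle(shuffled)
            assert select_main_chain(shuffled, g, counts) == ref

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            select_main_chain([], graph("C"))


class TestBackboneInvariants:
    def test_no_accepted_backbone_violates_bounds(self, analyzed_fixtures):
        for _, analysis in analyzed_fixtures.values():
            for frag in analysis.fragments:
                for bb in frag.backbones:
                    assert 5 <= bb.group.n_c <= 12
                    assert bb.group.branch_count <= 1
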