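"""Molecular graph substrate for backbone perception.

Thin wrapper around an RDKit molecule exposing the graph-level views the
extraction algorithm needs: atoms, bonds, connected components and the SSSR
ring list.  All perception (aromaticity, implicit hydrogens, ring finding)
is delegated to RDKit; this class only caches derived, purely topological
information.  Coordinates and stereochemistry are deliberately ignored by
every downstream rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from rdkit import Chem

#: elements regarded as "organic" for modification classification purposes.
#: Phosphorus and sulfur are included so that phosphorylated and sulfated
#: glycans survive extraction; Si, Se, B and metals mark a modification as
#: non-glycan.
ORGANIC_ELEMENTS = frozenset(
    {"C", "H", "N", "O", "P", "S", "F", "Cl", "Br", "I"}
)

HALOGENS = frozenset({"F", "Cl", "Br", "I"})


@dataclass(frozen=True)
class AtomRecord:
    index: int
    element: str
    formal_charge: int
    isotope: int
    implicit_hs: int
    aromatic: bool


@dataclass(frozen=True)
class BondRecord:
    atoms: tuple[int, int]
    order: float  # 1, 2, 3 or 1.5 (aromatic)


@dataclass
class MolecularGraph:
    """A molecule as an annotated undirected graph.

    Atom indices are the RDKit atom indices of ``rdmol`` and stay stable for
    the lifetime of the object.  Implicit hydrogens are materialized only as
    per-atom counts, never as graph nodes.
    """

    rdmol: Chem.Mol
    atoms: list[AtomRecord] = field(init=False)
    bonds: list[BondRecord] = field(init=False)
    components: list[frozenset[int]] = field(init=False)
    rings: list[tuple[int, ...]] = field(init=False)

    def __post_init__(self) -> None:
        mol = self.rdmol
        self.atoms = [
            AtomRecord(
                index=a.GetIdx(),
                element=a.GetSymbol(),
                formal_charge=a.GetFormalCharge(),
                isotope=a.GetIsotope(),
                implicit_hs=a.GetTotalNumHs(),
                aromatic=a.GetIsAromatic(),
            )
            for a in mol.GetAtoms()
        ]
        self.bonds = [
            BondRecord(
                atoms=(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                order=(1.5 if b.GetIsAromatic() else b.GetBondTypeAsDouble()),
            )
            for b in mol.GetBonds()
        ]
        frags = Chem.GetMolFrags(mol)
        self.components = [frozenset(f) for f in frags]
        self.rings = [tuple(r) for r in mol.GetRingInfo().AtomRings()]

    # -- convenience accessors -------------------------------------------

    @classmethod
    def from_smiles(cls, smiles: str) -> "MolecularGraph":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparsable SMILES: {smiles!r}")
        return cls(mol)

    def atom(self, idx: int) -> Chem.Atom:
        return self.rdmol.GetAtomWithIdx(idx)

    def element(self, idx: int) -> str:
        return self.rdmol.GetAtomWithIdx(idx).GetSymbol()

    def neighbors(self, idx: int) -> list[int]:
        return [n.GetIdx() for n in self.rdmol.GetAtomWithIdx(idx).GetNeighbors()]

    def bond_order(self, i: int, j: int) -> float:
        b = self.rdmol.GetBondBetweenAtoms(i, j)
        if b is None:
            raise KeyError(f"no bond between atoms {i} and {j}")
        return 1.5 if b.GetIsAromatic() else b.GetBondTypeAsDouble()

    def carbon_indices(self) -> set[int]:
        return {a.index for a in self.atoms if a.element == "C"}

    def rings_containing(self, idx: int) -> list[tuple[int, ...]]:
        return [r for r in self.rings if idx in r]

    def is_pi_cyclic(self, idx: int) -> bool:
        """True for atoms in aromatic rings or fully conjugated rings.

        Covers nucleobases, flavonoid cores and quinone-like rings while
        leaving partially saturated heterocycles (pyranoses, lactones,
        enone-containing anhydro sugars) untouched.
        """
        atom = self.atom(idx)
        if atom.GetIsAromatic():
            return True
        for ring in self.rings_containing(idx):
            if all(
                self.atom(i).GetHybridization()
                in (
                    Chem.HybridizationType.SP2,
                    Chem.HybridizationType.SP,
                )
                for i in ring
            ):
                return True
        return False

    def is_in_carbocycle(self, idx: int) -> bool:
        """True if the atom belongs to an SSSR ring made only of carbons."""
        for ring in self.rings_containing(idx):
            if all(self.element(i) == "C" for i in ring):
                return True
        return False

    def heavy_degree(self, idx: int) -> int:
        return self.rdmol.GetAtomWithIdx(idx).GetDegree()

    def num_heavy_atoms(self) -> int:
        return self.rdmol.GetNumAtoms()

    def canonical_ranks(self) -> list[int]:
        return list(Chem.CanonicalRankAtoms(self.rdmol, breakTies=True))


def induced_carbon_adjacency(
    graph: MolecularGraph, carbons: Iterable[int]
) -> dict[int, list[int]]:
    """Adjacency over C-C single/double/triple bonds within ``carbons``."""
    cs = set(carbons)
    adj: dict[int, list[int]] = {c: [] for c in cs}
    for c in cs:
        for n in graph.neighbors(c):
            if n in cs:
                adj[c].append(n)
    return adj
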