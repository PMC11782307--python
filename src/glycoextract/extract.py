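"""Modification partitioning, aglycone excision and glycan assembly.

Once backbones are accepted, every remaining heavy atom belongs to exactly
one *modification*: a connected atom group hanging off (or bridging) the
backbone chains.  Each modification is classified as

* ``substituent`` -- attached to a single backbone, kept;
* ``linkage``     -- attached to two or more backbones, kept;
* ``non_glycan``  -- an aglycone or other excluded group, excised.

A modification is non-glycan when every attachment is at an anomeric
carbon (the classic aglycone of a glycoside), when it contains a
non-organic atom, when it has too many branches (default 5), or when it
contains a large SSSR ring (default 10-membered or larger; macrolides).

Excision replaces each atom of the excised modification that touches a
backbone carbon with an oxygen, whatever element it was, and deletes the
rest.  Because the glycosidic oxygen itself is the touching atom in the
common case, excising an aglycone leaves a hydroxyl at the anomeric
position, and a bridge whose single oxygen touches two backbones (e.g.
trehalose) survives intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from rdkit import Chem

from .chains import (
    ANOMER,
    CandidacyVerdict,
    CarbonGroup,
    ChainCandidate,
    check_candidacy,
    enumerate_chains,
    eligible_carbons,
    find_carbon_groups,
    select_main_chain,
)
from .graph import ORGANIC_ELEMENTS, MolecularGraph
from .modcount import (
    ModificationCountBreakdown,
    ScoringScheme,
    ThresholdPolicy,
    compute_threshold,
    count_modifications,
)
from .molio import screen

SUBSTITUENT = "substituent"
LINKAGE = "linkage"
NON_GLYCAN = "non_glycan"


@dataclass(frozen=True)
class ExtractionOptions:
    with_aglycone: bool = False
    max_mod_branches: int = 5
    max_mod_ring: int = 10
    organic_elements: frozenset[str] = ORGANIC_ELEMENTS
    # config hook for the proposed saccharolipid rule (off by default:
    # acylated sugar backbones are extracted as monosaccharide residues)
    forbid_long_acyl_on_non_anomeric: bool = False

    def __post_init__(self):
        if self.max_mod_branches <= 0 or self.max_mod_ring <= 0:
            raise ValueError("modification thresholds must be positive")


@dataclass(frozen=True)
class ModFeatures:
    branch_count: int
    max_sssr_ring_size: Optional[int]
    elements: frozenset[str]
    anomeric_only: bool

    def has_non_organic(self, organic: frozenset[str] = ORGANIC_ELEMENTS) -> bool:
        return bool(self.elements - organic)


@dataclass(frozen=True)
class Attachment:
    backbone_index: int
    locant: int  # 1-based position on the backbone main chain
    connecting_atom: int  # modification-side atom
    backbone_atom: int


@dataclass(frozen=True)
class Modification:
    atom_indices: frozenset[int]
    attachments: tuple[Attachment, ...]
    features: ModFeatures
    mclass: str = ""


@dataclass(frozen=True)
class AcceptedBackbone:
    group: CarbonGroup
    chain: ChainCandidate
    breakdown: ModificationCountBreakdown

    @property
    def anomeric_atom(self) -> Optional[int]:
        if chain_pos := self.chain.anomeric_position:
            if self.chain.anomeric_status == ANOMER:
                return self.chain.ordered_carbons[chain_pos - 1]
        return None


@dataclass
class GlycanFragment:
    """An extracted glycan: backbones plus their retained modifications."""

    graph: MolecularGraph
    atom_map: dict[int, int]  # fragment atom index -> parent atom index
    backbones: list[AcceptedBackbone]
    modifications: list[Modification]
    excision_caps: list[int]  # parent indices of oxygen-capped atoms
    aglycone_atoms: frozenset[int] = frozenset()

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.graph.rdmol)

    @property
    def parent_atoms(self) -> frozenset[int]:
        return frozenset(self.atom_map.values())


@dataclass
class GroupAssessment:
    group: CarbonGroup
    verdict: CandidacyVerdict
    best_chain: Optional[ChainCandidate] = None
    breakdown: Optional[ModificationCountBreakdown] = None
    threshold: Optional[int] = None


@dataclass
class RecordAnalysis:
    graph: MolecularGraph
    screening: "object"
    groups: list[GroupAssessment] = field(default_factory=list)
    modifications: list[Modification] = field(default_factory=list)
    fragments: list[GlycanFragment] = field(default_factory=list)
    rejection_category: Optional[str] = None


# ---------------------------------------------------------------------------
# modification perception
# ---------------------------------------------------------------------------

def extract_modifications(
    mol: MolecularGraph, backbones: Sequence[AcceptedBackbone]
) -> list[Modification]:
    """Partition all non-backbone heavy atoms into connected modifications.

    Branch carbons of selected chains are modification moieties, so only
    main-chain carbons count as backbone atoms here.
    """
    backbone_atoms: dict[int, tuple[int, int]] = {}
    for bi, bb in enumerate(backbones):
        for pos, a in enumerate(bb.chain.ordered_carbons, start=1):
            backbone_atoms[a] = (bi, pos)

    rest = [
        a.index for a in mol.atoms if a.index not in backbone_atoms
    ]
    rest_set = set(rest)
    seen: set[int] = set()
    mods: list[Modification] = []
    for start in rest:
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            v = stack.pop()
            for w in mol.neighbors(v):
                if w in rest_set and w not in comp:
                    comp.add(w)
                    stack.append(w)
        seen |= comp
        attachments = []
        for a in sorted(comp):
            for w in mol.neighbors(a):
                if w in backbone_atoms:
                    bi, pos = backbone_atoms[w]
                    attachments.append(Attachment(bi, pos, a, w))
        mods.append(
            Modification(
                atom_indices=frozenset(comp),
                attachments=tuple(attachments),
                features=_features(mol, comp, attachments, backbones),
            )
        )
    ranks = mol.canonical_ranks()
    mods.sort(key=lambda m: min(ranks[i] for i in m.atom_indices))
    return mods


def _features(
    mol: MolecularGraph,
    comp: set[int],
    attachments: list[Attachment],
    backbones: Sequence[AcceptedBackbone],
) -> ModFeatures:
    branch_count = sum(1 for a in comp if mol.heavy_degree(a) >= 3)
    ring_sizes = [len(r) for r in mol.rings if set(r) <= comp]
    anomeric_atoms = {
        bb.anomeric_atom for bb in backbones if bb.anomeric_atom is not None
    }
    anomeric_only = bool(attachments) and all(
        att.backbone_atom in anomeric_atoms for att in attachments
    )
    return ModFeatures(
        branch_count=branch_count,
        max_sssr_ring_size=max(ring_sizes) if ring_sizes else None,
        elements=frozenset(mol.element(a) for a in comp),
        anomeric_only=anomeric_only,
    )


def classify_modification(
    m: Modification,
    backbones: Sequence[AcceptedBackbone],
    options: ExtractionOptions | None = None,
) -> str:
    """Classify a modification as substituent, linkage or non-glycan."""
    opts = options or ExtractionOptions()
    f = m.features
    if not m.attachments:
        return NON_GLYCAN  # disconnected component: never part of a glycan
    if f.anomeric_only:
        return NON_GLYCAN
    if f.has_non_organic(opts.organic_elements):
        return NON_GLYCAN
    if f.branch_count >= opts.max_mod_branches:
        return NON_GLYCAN
    if f.max_sssr_ring_size is not None and f.max_sssr_ring_size >= opts.max_mod_ring:
        return NON_GLYCAN
    n_backbones = len({att.backbone_index for att in m.attachments})
    return LINKAGE if n_backbones >= 2 else SUBSTITUENT


# ---------------------------------------------------------------------------
# excision and fragment assembly
# ---------------------------------------------------------------------------

def _transmute_to_oxygen(atom: Chem.Atom) -> None:
    atom.SetAtomicNum(8)
    atom.SetFormalCharge(0)
    atom.SetIsAromatic(False)
    atom.SetIsotope(0)
    atom.SetNoImplicit(False)
    atom.SetNumExplicitHs(0)
    atom.SetNumRadicalElectrons(0)


def excise_non_glycan(
    mol: MolecularGraph,
    backbones: Sequence[AcceptedBackbone],
    mods: Sequence[Modification],
    options: ExtractionOptions | None = None,
) -> list[GlycanFragment]:
    """Remove non-glycan modifications, cap with oxygen, split fragments."""
    opts = options or ExtractionOptions()
    backbone_atoms = {
        a for bb in backbones for a in bb.chain.ordered_carbons
    }
    if not backbone_atoms:
        return []

    rw = Chem.RWMol(mol.rdmol)
    caps: set[int] = set()
    removed: set[int] = set()
    aglycone: set[int] = set()
    for m in mods:
        if m.mclass != NON_GLYCAN:
            continue
        aglycone |= set(m.atom_indices)
        if opts.with_aglycone:
            continue  # exclusions turned off: aglycones stay in place
        connecting = {att.connecting_atom for att in m.attachments}
        removed |= set(m.atom_indices) - connecting
        for a in connecting:
            _transmute_to_oxygen(rw.GetAtomWithIdx(a))
            caps.add(a)

    keep = [i for i in range(rw.GetNumAtoms()) if i not in removed]
    for i in sorted(removed, reverse=True):
        rw.RemoveAtom(i)
    pruned = rw.GetMol()
    Chem.SanitizeMol(pruned)
    new_to_old = {new: old for new, old in enumerate(keep)}

    frag_indices = Chem.GetMolFrags(pruned)
    fragments: list[GlycanFragment] = []
    for fi in frag_indices:
        parent_atoms = {new_to_old[i] for i in fi}
        bb_here = [
            bb
            for bb in backbones
            if set(bb.chain.ordered_carbons) <= parent_atoms
        ]
        if not bb_here:
            continue
        sub = Chem.RWMol(pruned)
        for i in sorted(set(range(pruned.GetNumAtoms())) - set(fi), reverse=True):
            sub.RemoveAtom(i)
        frag_mol = sub.GetMol()
        Chem.SanitizeMol(frag_mol)
        atom_map = {
            k: new_to_old[orig] for k, orig in enumerate(sorted(fi))
        }
        mods_here = [
            m
            for m in mods
            if m.mclass in (SUBSTITUENT, LINKAGE)
            and m.atom_indices & parent_atoms
        ]
        fragments.append(
            GlycanFragment(
                graph=MolecularGraph(frag_mol),
                atom_map=atom_map,
                backbones=bb_here,
                modifications=mods_here,
                excision_caps=sorted(caps & parent_atoms),
                aglycone_atoms=frozenset(aglycone & parent_atoms),
            )
        )
    fragments.sort(key=lambda f: (-len(f.backbones), f.smiles))
    return fragments


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def analyze(
    mol: MolecularGraph,
    options: ExtractionOptions | None = None,
    policy: ThresholdPolicy | None = None,
    scheme: ScoringScheme | None = None,
) -> RecordAnalysis:
    """Run the full extraction pipeline with a complete audit trail."""
    opts = options or ExtractionOptions()
    policy = policy or ThresholdPolicy()
    scheme = scheme or ScoringScheme()

    screening = screen(mol)
    analysis = RecordAnalysis(graph=mol, screening=screening)
    if not screening.accepted:
        analysis.rejection_category = "screened_out"
        return analysis

    accepted: list[AcceptedBackbone] = []
    for group in find_carbon_groups(mol):
        assess = GroupAssessment(
            group=group, verdict=check_candidacy(group, None, mol)
        )
        if not assess.verdict.passed:
            analysis.groups.append(assess)
            continue
        chains_ = enumerate_chains(group, mol)
        counts = {ch: count_modifications(ch, mol, scheme) for ch in chains_}
        verdicts = {
            ch: check_candidacy(group, ch, mol, counts[ch], policy)
            for ch in chains_
        }
        passing = [ch for ch in chains_ if verdicts[ch].passed]
        pool = passing or chains_
        best = select_main_chain(pool, mol, counts)
        assess.best_chain = best
        assess.breakdown = counts[best]
        assess.threshold = compute_threshold(group.n_c, policy)
        assess.verdict = verdicts[best]
        analysis.groups.append(assess)
        if passing:
            accepted.append(
                AcceptedBackbone(
                    group=group, chain=best, breakdown=counts[best]
                )
            )

    if accepted:
        mods = extract_modifications(mol, accepted)
        mods = [
            replace(m, mclass=classify_modification(m, accepted, opts))
            for m in mods
        ]
        analysis.modifications = mods
        analysis.fragments = excise_non_glycan(mol, accepted, mods, opts)

    if not analysis.fragments:
        analysis.rejection_category = _rejection_category(mol, analysis)
    return analysis


def _rejection_category(
    mol: MolecularGraph, analysis: RecordAnalysis
) -> str:
    _, exclusions = eligible_carbons(mol)
    if "pi_cyclic" in exclusions or any(a.aromatic for a in mol.atoms):
        return "aromatic_or_pi_cyclic"
    if not any(g.group.n_c >= 5 for g in analysis.groups):
        if "carbocycle" in exclusions:
            return "carbocycle"
        return "chain_too_short"
    if any(
        "modification_count" in g.verdict.failed_conditions
        for g in analysis.groups
    ):
        return "modification_count_exceeded"
    return "structure_rules"


def extract_glycans(
    mol: MolecularGraph,
    options: ExtractionOptions | None = None,
    policy: ThresholdPolicy | None = None,
    scheme: ScoringScheme | None = None,
) -> list[GlycanFragment]:
    """Extract all glycan fragments from a molecule (empty list if none)."""
    return analyze(mol, options, policy, scheme).fragments
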