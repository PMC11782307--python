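"""Candidate monosaccharide backbone perception.

A monosaccharide backbone is modelled as a linear carbon chain.  Candidate
chains are found by first collecting *carbon groups* -- maximal connected
sets of chain-eligible carbons -- and then enumerating every maximal simple
path through each group.  Eligibility and group-level candidacy follow the
default structural conditions:

* 5--12 carbons per group (branch carbons included),
* at most one branch,
* no carbon inside or directly bonded to a carbocycle,
* no carbon that is, or is bonded to, a pi-cyclic (aromatic / fully
  conjugated ring) atom,
* no chain carbon in a 3- or 4-membered cyclic ether,
* modification count within the length-dependent threshold (scored in
  :mod:`glycoextract.modcount`).

Sugar rings (the endocyclic C-O-C of pyranoses/furanoses) are traversed as
open chains: paths run over C-C bonds only and the hemiacetal oxygen is
treated as an anomeric feature, not a path edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .graph import MolecularGraph, induced_carbon_adjacency

ANOMER = "anomer"
POTENTIAL_ANOMER = "potential_anomer"
NO_ANOMER = "none"

HETERO_SUBSTITUENT = frozenset({"O", "N", "S"})


@dataclass(frozen=True)
class CarbonGroup:
    """A maximal connected set of backbone-eligible carbons."""

    carbon_indices: frozenset[int]
    branch_count: int

    @property
    def n_c(self) -> int:
        return len(self.carbon_indices)


@dataclass(frozen=True)
class ChainCandidate:
    """One linear ordering (main chain) through a carbon group."""

    ordered_carbons: tuple[int, ...]
    branch_carbons: frozenset[int]
    anomeric_status: str
    anomeric_position: Optional[int]  # 1-based locant on ordered_carbons

    @property
    def length(self) -> int:
        return len(self.ordered_carbons)

    @property
    def all_carbons(self) -> frozenset[int]:
        return frozenset(self.ordered_carbons) | self.branch_carbons

    def locant(self, atom_idx: int) -> int:
        return self.ordered_carbons.index(atom_idx) + 1


@dataclass(frozen=True)
class CandidacyVerdict:
    passed: bool
    failed_conditions: frozenset[str]


# ---------------------------------------------------------------------------
# carbon group perception
# ---------------------------------------------------------------------------

def eligible_carbons(mol: MolecularGraph) -> tuple[set[int], set[str]]:
    """Backbone-eligible carbons plus codes for the exclusions applied."""
    exclusions: set[str] = set()
    eligible: set[int] = set()
    carbons = mol.carbon_indices()
    for c in carbons:
        if mol.is_in_carbocycle(c):
            exclusions.add("carbocycle")
            continue
        if mol.is_pi_cyclic(c):
            exclusions.add("pi_cyclic")
            continue
        bonded_bad = False
        for n in mol.neighbors(c):
            if mol.element(n) == "C" and mol.is_in_carbocycle(n):
                exclusions.add("carbocycle")
                bonded_bad = True
            if mol.is_pi_cyclic(n):
                exclusions.add("pi_cyclic")
                bonded_bad = True
        if bonded_bad:
            continue
        eligible.add(c)
    return eligible, exclusions


def find_carbon_groups(mol: MolecularGraph) -> list[CarbonGroup]:
    """Maximal connected sets of chain-eligible carbons.

    Returned in a deterministic order (smallest canonical atom rank first)
    so downstream processing is invariant under input atom permutation.
    """
    eligible, _ = eligible_carbons(mol)
    adj = induced_carbon_adjacency(mol, eligible)
    seen: set[int] = set()
    groups: list[CarbonGroup] = []
    for start in eligible:
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            v = stack.pop()
            for w in adj[v]:
                if w not in comp:
                    comp.add(w)
                    stack.append(w)
        seen |= comp
        branch = sum(max(0, len([w for w in adj[v] if w in comp]) - 2) for v in comp)
        groups.append(CarbonGroup(frozenset(comp), branch))
    ranks = mol.canonical_ranks()
    groups.sort(key=lambda g: min(ranks[i] for i in g.carbon_indices))
    return groups


# ---------------------------------------------------------------------------
# anomeric perception
# ---------------------------------------------------------------------------

def _single_bonded_hetero(mol: MolecularGraph, c: int, chain: set[int]) -> list[int]:
    out = []
    for n in mol.neighbors(c):
        if n in chain:
            continue
        if mol.element(n) in HETERO_SUBSTITUENT and mol.bond_order(c, n) == 1.0:
            out.append(n)
    return out


def carbonyl_oxygen(mol: MolecularGraph, c: int) -> Optional[int]:
    """Index of a double-bonded O on carbon ``c`` (None if absent)."""
    for n in mol.neighbors(c):
        if mol.element(n) == "O" and mol.bond_order(c, n) == 2.0:
            return n
    return None


def is_plain_carbonyl(mol: MolecularGraph, c: int, chain: set[int]) -> bool:
    """Aldehyde/ketone carbon: C=O with no single-bonded O/N/S attached.

    Carboxyl-, ester- and amide-type carbonyls are excluded -- those are
    scored as replacements, not as (potential) anomeric carbonyls.
    """
    if carbonyl_oxygen(mol, c) is None:
        return False
    return not _single_bonded_hetero(mol, c, chain)


def ring_anomeric_centers(
    mol: MolecularGraph, chain_carbons: Iterable[int]
) -> list[int]:
    """Hemiacetal/hemiketal/acetal carbons on the chain.

    A chain carbon qualifies when it bears two or more single-bonded O/N/S
    substituents, at least one of which sits in an SSSR ring that also
    contains another chain carbon (the endocyclic sugar-ring heteroatom).
    Glycosides (full acetals) qualify too -- the anomeric nature of the
    carbon does not depend on whether the exocyclic oxygen carries H or R.
    """
    chain = set(chain_carbons)
    centers = []
    for c in chain:
        hets = _single_bonded_hetero(mol, c, chain)
        if len(hets) < 2:
            continue
        for h in hets:
            for ring in mol.rings_containing(h):
                if c in ring and any(x in chain and x != c for x in ring):
                    centers.append(c)
                    break
            else:
                continue
            break
    return sorted(centers)


def _min_locant(chain: Sequence[int], atom: int) -> int:
    i = chain.index(atom)
    return min(i + 1, len(chain) - i)


def detect_anomeric(
    path: Sequence[int], mol: MolecularGraph
) -> tuple[str, Optional[int]]:
    """Anomeric status of a carbon path and the designated center's atom.

    Returns ``(status, atom_index)``.  The designated center is the ring
    anomeric carbon if any exists, else an open-chain aldehyde/ketone
    carbonyl; among equals, one with locant 1 or 2 is preferred (it incurs
    no anomer penalty), then the lowest locant.
    """
    chain = set(path)

    def pick(candidates: list[int]) -> int:
        common = [c for c in candidates if _min_locant(path, c) <= 2]
        pool = common or candidates
        return min(pool, key=lambda c: (_min_locant(path, c), path.index(c)))

    ring_centers = ring_anomeric_centers(mol, path)
    if ring_centers:
        return ANOMER, pick(ring_centers)
    carbonyls = [c for c in path if is_plain_carbonyl(mol, c, chain)]
    if carbonyls:
        return POTENTIAL_ANOMER, pick(carbonyls)
    return NO_ANOMER, None


# ---------------------------------------------------------------------------
# chain enumeration
# ---------------------------------------------------------------------------

def _maximal_simple_paths(adj: dict[int, list[int]]) -> list[tuple[int, ...]]:
    """All maximal simple paths in a small graph (depth-first extension)."""
    paths: set[tuple[int, ...]] = set()

    def extend(path: list[int], visited: set[int]) -> None:
        tip = path[-1]
        nexts = [w for w in adj[tip] if w not in visited]
        head_nexts = [w for w in adj[path[0]] if w not in visited]
        if not nexts:
            if head_nexts:
                return  # extendable at the head; the reversed DFS covers it
            key = tuple(path) if tuple(path) <= tuple(reversed(path)) else tuple(
                reversed(path)
            )
            paths.add(key)
            return
        for w in nexts:
            path.append(w)
            visited.add(w)
            extend(path, visited)
            visited.remove(w)
            path.pop()

    for start in adj:
        extend([start], {start})
    return sorted(paths)


def _orient(
    path: tuple[int, ...],
    designated: Optional[int],
    mol: MolecularGraph,
) -> tuple[int, ...]:
    """Choose chain direction: lower anomeric locant, then canonical ranks."""
    fwd, rev = path, tuple(reversed(path))
    if designated is not None:
        lf = fwd.index(designated) + 1
        lr = rev.index(designated) + 1
        if lf != lr:
            return fwd if lf < lr else rev
    ranks = mol.canonical_ranks()
    return min(fwd, rev, key=lambda p: tuple(ranks[i] for i in p))


def enumerate_chains(
    group: CarbonGroup, mol: MolecularGraph
) -> list[ChainCandidate]:
    """Every maximal simple C-C path through the group, anomerics detected.

    The two orientations of an undirected path are collapsed into the one
    that gives the designated (potential) anomeric carbon the lower locant.
    """
    adj = induced_carbon_adjacency(mol, group.carbon_indices)
    candidates = []
    for path in _maximal_simple_paths(adj):
        status, designated = detect_anomeric(path, mol)
        oriented = _orient(path, designated, mol)
        position = oriented.index(designated) + 1 if designated is not None else None
        candidates.append(
            ChainCandidate(
                ordered_carbons=oriented,
                branch_carbons=frozenset(group.carbon_indices) - frozenset(oriented),
                anomeric_status=status,
                anomeric_position=position,
            )
        )
    return candidates


# ---------------------------------------------------------------------------
# candidacy and main-chain selection
# ---------------------------------------------------------------------------

def in_small_cyclic_ether(mol: MolecularGraph, c: int) -> bool:
    """Epoxide/oxetane membership: 3-/4-ring with one O, rest carbons."""
    for ring in mol.rings_containing(c):
        if len(ring) in (3, 4):
            elems = [mol.element(i) for i in ring]
            if elems.count("O") == 1 and elems.count("C") == len(ring) - 1:
                return True
    return False


def check_candidacy(
    group: CarbonGroup,
    chain: Optional[ChainCandidate],
    mol: MolecularGraph,
    count=None,
    policy=None,
) -> CandidacyVerdict:
    """Apply the structural candidacy conditions to a group/chain pair.

    ``count``/``policy`` (a ModificationCountBreakdown and ThresholdPolicy)
    are only consulted when the structural conditions pass.
    """
    from .modcount import ThresholdPolicy, compute_threshold

    failed: set[str] = set()
    if not 5 <= group.n_c <= 12:
        failed.add("size")
    if group.branch_count > 1:
        failed.add("branches")
    if chain is not None and any(
        in_small_cyclic_ether(mol, c) for c in chain.ordered_carbons
    ):
        failed.add("small_cyclic_ether")
    if not failed and count is not None:
        policy = policy or ThresholdPolicy()
        if count.n_mod > compute_threshold(group.n_c, policy):
            failed.add("modification_count")
    return CandidacyVerdict(passed=not failed, failed_conditions=frozenset(failed))


_PRIORITY = {ANOMER: 0, POTENTIAL_ANOMER: 1, NO_ANOMER: 2}


def select_main_chain(
    candidates: Sequence[ChainCandidate],
    mol: MolecularGraph,
    counts: Optional[dict] = None,
) -> ChainCandidate:
    """Pick the unique best chain of a group.

    Priority: anomeric > potential anomeric > none, then longer chain, then
    lower modification count and lower modification locants, then the
    deterministic canonical-rank tie-break.  The winner's branch carbons
    are later treated as modification moieties.  The result is invariant to
    input order.
    """
    if not candidates:
        raise ValueError("select_main_chain requires at least one candidate")
    ranks = mol.canonical_ranks()

    def key(ch: ChainCandidate):
        breakdown = counts.get(ch) if counts else None
        n_mod = breakdown.n_mod if breakdown is not None else 0
        if breakdown is not None:
            mod_locants = tuple(
                i + 1
                for i, pc in enumerate(
                    breakdown.per_carbon[: ch.length]
                )
                if pc.replacement or pc.unsaturation
            )
        else:
            mod_locants = ()
        return (
            _PRIORITY[ch.anomeric_status],
            -ch.length,
            n_mod,
            mod_locants,
            tuple(ranks[i] for i in ch.ordered_carbons),
        )

    return min(candidates, key=key)
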