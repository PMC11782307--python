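"""Modification-count scoring of candidate backbones.

The modification count N_mod measures how far a carbon chain deviates from
the basic state of a monosaccharide backbone: one (potential) carbonyl at
position 1 or 2 and exactly one hydroxyl on every other carbon (an aldose
or 2-ketose).  Five contribution types are summed:

    N_mod = sum_i (N_replacement_i + N_unsaturation_i)
            + N_ring + 2 * N_extra_carbonyl + N_anomer_penalty

and compared against a length-dependent threshold

    theta(n_c) = min(n_c - offset, cap)        (default offset 3, cap 5)

where n_c counts all carbons of the group, branch carbons included.  A
chain is rejected only when N_mod strictly exceeds theta(n_c); equality
passes, which admits the most-modified sugars with SNFG symbols
(5,7-diamino-3,5,7,9-tetradeoxy-non-2-ulosonic acid scores exactly 5 on
the nonose cap).

Per-feature scores (all configurable, defaults in :class:`ScoringScheme`):

* deoxy carbon (no O/N/S substituent, saturated, not a carbonyl): +1
* hydroxyl replaced by an N-, S-, halogen- or other hetero-linked
  substituent: +1 per substituent
* terminal carboxyl/ester carbon: +1 (a semi-standard state -- sugar acids
  remain monosaccharide-like)
* amide carbon (carboxyl further N-substituted, e.g. a peptide bond): +2
* carbon branch attached to the chain: +1 at the bearing carbon (the
  branch itself becomes a modification moiety)
* C=C between chain carbons: +1; C#C: +2 (attributed to the lower locant)
* anhydro/lactone ring among chain atoms and their oxygens: +1 each,
  excluding the single hemiacetal/hemiketal ring of the anomeric center
* extra aldehyde/ketone carbonyl beyond the designated (potential)
  anomeric one: counted once, weighted x2 in the total
* anomer penalty: +1 when the (potential) anomeric carbonyl sits at a
  locant above 2, or when the chain has none at all (alditols); never
  stacked.

Scoring is purely constitutional: stereoisomers score identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .chains import ANOMER, NO_ANOMER, ChainCandidate
from .graph import MolecularGraph


@dataclass(frozen=True)
class ThresholdPolicy:
    offset: int = 3
    cap: int = 5


@dataclass(frozen=True)
class ScoringScheme:
    deoxy: int = 1
    hetero_substituent: int = 1
    extra_oxygen: int = 1
    carbon_substituent: int = 1
    carboxyl: int = 1
    amide: int = 2
    double_bond: int = 1
    triple_bond: int = 2
    ring: int = 1
    anomer_penalty: int = 1


@dataclass(frozen=True)
class PerCarbonCount:
    atom_index: int
    replacement: int
    unsaturation: int


@dataclass(frozen=True)
class ModificationCountBreakdown:
    """Full decomposition of N_mod for one chain candidate.

    ``per_carbon`` covers the main-chain positions first (in locant order)
    followed by any branch carbons; branch carbons are scored with the same
    substituent rules.
    """

    per_carbon: tuple[PerCarbonCount, ...]
    n_ring: int
    n_extra_carbonyl: int
    n_anomer_penalty: int

    @property
    def n_mod(self) -> int:
        return (
            sum(pc.replacement + pc.unsaturation for pc in self.per_carbon)
            + self.n_ring
            + 2 * self.n_extra_carbonyl
            + self.n_anomer_penalty
        )

    def replacement_at(self, atom_index: int) -> int:
        for pc in self.per_carbon:
            if pc.atom_index == atom_index:
                return pc.replacement
        raise KeyError(f"atom {atom_index} not on this chain")


def compute_threshold(n_c: int, policy: ThresholdPolicy | None = None) -> int:
    """theta(n_c) = min(n_c - offset, cap); defined for 5 <= n_c <= 12."""
    policy = policy or ThresholdPolicy()
    if not 5 <= n_c <= 12:
        raise ValueError(f"n_c={n_c} outside the candidacy range [5, 12]")
    return min(n_c - policy.offset, policy.cap)


def exceeds_threshold(
    count: ModificationCountBreakdown,
    n_c: int,
    policy: ThresholdPolicy | None = None,
) -> bool:
    """Strictly-greater comparison: equality still passes."""
    return count.n_mod > compute_threshold(n_c, policy)


def _classify_neighbors(mol: MolecularGraph, c: int, candidate: set[int]):
    """Substituent tallies for one candidate carbon."""
    o_single = o_double = hetero = carbon_sub = 0
    for n in mol.neighbors(c):
        if n in candidate:
            continue
        elem = mol.element(n)
        order = mol.bond_order(c, n)
        if elem == "O":
            if order == 2.0:
                o_double += 1
            else:
                o_single += 1
        elif elem == "C":
            carbon_sub += 1
        else:
            hetero += 1
    return o_single, o_double, hetero, carbon_sub


def count_modifications(
    chain: ChainCandidate,
    mol: MolecularGraph,
    scheme: ScoringScheme | None = None,
) -> ModificationCountBreakdown:
    """Score a chain candidate against the basic monosaccharide state."""
    s = scheme or ScoringScheme()
    main = chain.ordered_carbons
    ranks = mol.canonical_ranks()
    branch = sorted(chain.branch_carbons, key=lambda i: ranks[i])
    carbons = list(main) + branch
    candidate = set(carbons)
    designated = (
        main[chain.anomeric_position - 1]
        if chain.anomeric_position is not None
        else None
    )

    # unsaturation along consecutive main-chain bonds, attributed to the
    # lower-locant carbon
    unsat = {c: 0 for c in carbons}
    for a, b in zip(main, main[1:]):
        order = mol.bond_order(a, b)
        if order == 2.0:
            unsat[a] += s.double_bond
        elif order == 3.0:
            unsat[a] += s.triple_bond

    n_extra_carbonyl = 0
    per_carbon: list[PerCarbonCount] = []
    for c in carbons:
        # a branch carbon hanging off the main chain replaces the bearing
        # carbon's hydroxyl, so it is counted as a substituent there; the
        # branch carbon itself is scored against the whole candidate set
        exclude = set(main) if c in set(main) else candidate
        o_single, o_double, hetero, carbon_sub = _classify_neighbors(
            mol, c, exclude
        )
        rep = 0
        single_ns = [
            n
            for n in mol.neighbors(c)
            if n not in candidate
            and mol.element(n) in ("N", "S")
        ]
        if o_double:
            if single_ns:
                # amide / thioester-type carbonyl
                rep += s.amide + max(0, hetero - len(single_ns))
                rep += max(0, o_single) * s.extra_oxygen
            elif o_single:
                # carboxyl or ester (incl. the lactone carbonyl carbon)
                rep += s.carboxyl + max(0, o_single - 1) * s.extra_oxygen
                rep += hetero * s.hetero_substituent
            elif c == designated:
                rep += 0  # the reference (potential) anomeric carbonyl
            else:
                n_extra_carbonyl += 1
                rep += hetero * s.hetero_substituent
            rep += carbon_sub * s.carbon_substituent
        else:
            allowed_o = (
                2
                if (c == designated and chain.anomeric_status == ANOMER)
                else 1
            )
            rep += hetero * s.hetero_substituent
            rep += carbon_sub * s.carbon_substituent
            rep += max(0, o_single - allowed_o) * s.extra_oxygen
            if (
                o_single == 0
                and hetero == 0
                and carbon_sub == 0
                and unsat[c] == 0
                and not any(
                    n in candidate and mol.bond_order(c, n) > 1.0
                    for n in mol.neighbors(c)
                )
            ):
                rep += s.deoxy  # hydroxyl replaced by hydrogen
        per_carbon.append(PerCarbonCount(c, rep, unsat[c]))

    n_ring = _count_rings(mol, candidate, designated, chain)
    n_penalty = _anomer_penalty(chain, s)
    return ModificationCountBreakdown(
        per_carbon=tuple(per_carbon),
        n_ring=n_ring * s.ring,
        n_extra_carbonyl=n_extra_carbonyl,
        n_anomer_penalty=n_penalty,
    )


def _anomer_penalty(chain: ChainCandidate, s: ScoringScheme) -> int:
    if chain.anomeric_status == NO_ANOMER:
        return s.anomer_penalty  # alditol / acid with no carbonyl at all
    if chain.anomeric_position is not None and chain.anomeric_position > 2:
        return s.anomer_penalty  # uncommon anomeric position
    return 0


def _count_rings(
    mol: MolecularGraph,
    candidate: set[int],
    designated: Optional[int],
    chain: ChainCandidate,
) -> int:
    """Anhydro/lactone rings: SSSR rings over chain carbons and oxygens.

    The single hemiacetal/hemiketal ring through the designated anomeric
    center is not a modification and is excluded.
    """
    qualifying = []
    for ring in mol.rings:
        atoms_ok = all(i in candidate or mol.element(i) == "O" for i in ring)
        if atoms_ok and any(i in candidate for i in ring):
            qualifying.append(ring)
    exclude = 0
    if designated is not None and chain.anomeric_status == ANOMER:
        anomeric_rings = [r for r in qualifying if designated in r]
        if anomeric_rings:
            exclude = 1
    return max(0, len(qualifying) - exclude)
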