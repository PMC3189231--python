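"""Pedigree representation, kinship, member classification and
transmission-path inference.

The kinship coefficient phi(i, j) is the probability that one allele drawn
at random from i and one from j are identical by descent.  For non-inbred
pairs the expected autosomal genome fraction shared IBD is 2*phi: 0.5 for
full siblings, 0.25 for avuncular pairs, 0.125 for first cousins and
0.03125 for second cousins — the chance-sharing baselines that make
co-segregation across distant affected relatives informative.

Transmission inference treats genotype-unknown individuals (no DNA) as
permissive: a descent path may pass through them, since extended pedigrees
typically have many untyped members, but never through a typed
non-carrier.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Set, Tuple

logger = logging.getLogger(__name__)

AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNKNOWN = "unknown"


@dataclass
class Individual:
    iid: str
    father: Optional[str] = None
    mother: Optional[str] = None
    sex: str = "0"  # "1" male, "2" female, "0" unknown
    affection: str = UNKNOWN
    dna_available: bool = False
    other_diagnoses: list = field(default_factory=list)

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


class PedigreeError(ValueError):
    pass


class Pedigree:
    """A validated family pedigree.

    Parent links must be acyclic and come in pairs: an individual has
    either both parents in the pedigree or none.  A single known parent is
    completed with a synthetic placeholder founder (logged).
    """

    def __init__(self, family_id: str, members: Iterable[Individual]):
        self.family_id = family_id
        self.members: Dict[str, Individual] = {}
        for m in members:
            if m.iid in self.members:
                raise PedigreeError(f"duplicate individual {m.iid!r} in family {family_id}")
            self.members[m.iid] = m
        self._complete_single_parents()
        self._validate_links()
        self._children: Dict[str, List[str]] = {i: [] for i in self.members}
        for m in self.members.values():
            for p in (m.father, m.mother):
                if p is not None:
                    self._children[p].append(m.iid)
        for v in self._children.values():
            v.sort()
        self._depth = self._compute_depths()
        self._kin_memo: Dict[Tuple[str, str], Fraction] = {}

    # -- construction helpers -------------------------------------------------

    def _complete_single_parents(self) -> None:
        extra = []
        for m in self.members.values():
            known = [p for p in (m.father, m.mother) if p is not None]
            for p in known:
                if p not in self.members and not any(e.iid == p for e in extra):
                    raise PedigreeError(
                        f"individual {m.iid!r} references unknown parent {p!r}"
                    )
            if len(known) == 1:
                placeholder = f"_ph_{m.iid}"
                logger.warning(
                    "family %s: individual %s has a single known parent; "
                    "adding placeholder founder %s",
                    self.family_id, m.iid, placeholder,
                )
                extra.append(Individual(placeholder, sex="0", affection=UNKNOWN))
                if m.father is None:
                    m.father = placeholder
                else:
                    m.mother = placeholder
        for e in extra:
            self.members[e.iid] = e

    def _validate_links(self) -> None:
        # cycle check via iterative ancestor walk
        state: Dict[str, int] = {}

        def visit(i: str, stack: Set[str]) -> None:
            if i in stack:
                raise PedigreeError(f"cycle in parent links at {i!r}")
            if state.get(i):
                return
            stack.add(i)
            m = self.members[i]
            for p in (m.father, m.mother):
                if p is not None:
                    visit(p, stack)
            stack.discard(i)
            state[i] = 1

        for i in self.members:
            visit(i, set())

    def _compute_depths(self) -> Dict[str, int]:
        depth: Dict[str, int] = {}

        def d(i: str) -> int:
            if i in depth:
                return depth[i]
            m = self.members[i]
            if m.is_founder:
                depth[i] = 0
            else:
                depth[i] = 1 + max(d(m.father), d(m.mother))
            return depth[i]

        for i in self.members:
            d(i)
        return depth

    # -- basic accessors ------------------------------------------------------

    def __contains__(self, iid: str) -> bool:
        return iid in self.members

    def __len__(self) -> int:
        return len(self.members)

    def individual(self, iid: str) -> Individual:
        try:
            return self.members[iid]
        except KeyError:
            raise PedigreeError(f"unknown individual {iid!r} in family {self.family_id}")

    def children_of(self, iid: str) -> List[str]:
        return self._children[iid]

    def depth(self, iid: str) -> int:
        return self._depth[iid]

    def founders(self) -> List[str]:
        return sorted(i for i, m in self.members.items() if m.is_founder)

    def affected_ids(self) -> List[str]:
        return sorted(i for i, m in self.members.items() if m.affection == AFFECTED)

    def genotyped_ids(self) -> List[str]:
        return sorted(i for i, m in self.members.items() if m.dna_available)

    def affected_with_dna(self) -> List[str]:
        return sorted(
            i for i, m in self.members.items()
            if m.affection == AFFECTED and m.dna_available
        )

    def descendants(self, iid: str) -> Set[str]:
        out: Set[str] = set()
        stack = [iid]
        while stack:
            for c in self._children[stack.pop()]:
                if c not in out:
                    out.add(c)
                    stack.append(c)
        return out

    def ancestors(self, iid: str) -> Set[str]:
        out: Set[str] = set()
        stack = [iid]
        while stack:
            m = self.members[stack.pop()]
            for p in (m.father, m.mother):
                if p is not None and p not in out:
                    out.add(p)
                    stack.append(p)
        return out

    def spouses_of(self, iid: str) -> List[str]:
        """Co-parents: individuals sharing at least one child with iid."""
        out = set()
        for c in self._children[iid]:
            m = self.members[c]
            for p in (m.father, m.mother):
                if p is not None and p != iid:
                    out.add(p)
        return sorted(out)

    # -- kinship --------------------------------------------------------------

    def kinship(self, i: str, j: str) -> Fraction:
        """Recursive kinship coefficient; founders unrelated, non-inbred."""
        self.individual(i), self.individual(j)
        return self._phi(i, j)

    def _phi(self, i: str, j: str) -> Fraction:
        key = (i, j) if i <= j else (j, i)
        if key in self._kin_memo:
            return self._kin_memo[key]
        a, b = self.members[i], self.members[j]
        if i == j:
            if a.is_founder:
                val = Fraction(1, 2)
            else:
                val = Fraction(1, 2) * (1 + self._phi(a.father, a.mother))
        else:
            # recurse on the deeper individual; an ancestor is always
            # strictly shallower, so this never recurses into a descendant
            if self._depth[i] < self._depth[j]:
                i, j, a, b = j, i, b, a
            if a.is_founder:
                val = Fraction(0)
            else:
                val = Fraction(1, 2) * (self._phi(a.father, j) + self._phi(a.mother, j))
        self._kin_memo[key] = val
        return val

    def expected_sharing(self, i: str, j: str) -> Fraction:
        """Expected autosomal fraction shared IBD, 2*phi, for a distinct
        non-inbred pair."""
        if i == j:
            raise PedigreeError("expected_sharing is defined for distinct pairs only")
        return 2 * self.kinship(i, j)

    # -- validation of the extended-family structure --------------------------

    def validate_extended_family(self) -> List[str]:
        """Warnings (not errors) when the family lacks the structure the
        analysis assumes: at least two affected members related no closer
        than an avuncular pair (expected sharing <= 0.25, > 0)."""
        warnings: List[str] = []
        aff = self.affected_ids()
        ok = False
        for i, j in itertools.combinations(aff, 2):
            s = self.expected_sharing(i, j)
            if 0 < s <= Fraction(1, 4):
                ok = True
                break
        if not ok:
            w = (
                f"family {self.family_id}: no affected avuncular-or-more-distant "
                f"pair found ({len(aff)} affected)"
            )
            warnings.append(w)
            logger.warning(w)
        # married-in individuals related to the blood line through a second path
        parts = self.classify_members()
        blood = set(parts[AFFECTED]) | set(parts["unaffected_blood"])
        for m in parts["married_in"]:
            # a married-in is trivially related to their own descendants;
            # a second path exists only via non-descendant blood members
            for b in blood - self.descendants(m) - {m}:
                if self.kinship(m, b) > 0:
                    w = (
                        f"family {self.family_id}: married-in {m} is also a blood "
                        f"relative of {b}"
                    )
                    warnings.append(w)
                    logger.warning(w)
        return warnings

    # -- member classification -------------------------------------------------

    def founding_couple(self) -> Optional[Tuple[str, str]]:
        """The parentless couple anchoring the lineage under analysis:
        the founder pair whose joint descendants include the most affected
        individuals (ties: most descendants, then lexicographic ids)."""
        couples = set()
        for m in self.members.values():
            if m.father is not None and m.mother is not None:
                fa, mo = self.members[m.father], self.members[m.mother]
                if fa.is_founder and mo.is_founder:
                    couples.add(tuple(sorted((m.father, m.mother))))
        if not couples:
            return None
        affected = set(self.affected_ids())
        best, best_key = None, None
        for c in sorted(couples):
            desc = self.descendants(c[0]) | self.descendants(c[1])
            key = (len(desc & affected), len(desc))
            if best is None or key > best_key:
                best, best_key = c, key
        return best

    def classify_members(self) -> Dict[str, List[str]]:
        """Partition members into affected / unaffected blood-line /
        married-in.  The blood line is the founding couple plus its
        descendants; affected individuals are in the affected partition
        regardless of lineage."""
        couple = self.founding_couple()
        blood: Set[str] = set()
        if couple is not None:
            blood = {couple[0], couple[1]}
            blood |= self.descendants(couple[0]) | self.descendants(couple[1])
        affected = set(self.affected_ids())
        unaffected_blood = sorted(blood - affected)
        married_in = sorted(set(self.members) - blood - affected)
        return {
            AFFECTED: sorted(affected),
            "unaffected_blood": unaffected_blood,
            "married_in": married_in,
        }

    # -- transmission inference -------------------------------------------------

    def infer_transmission(
        self,
        carriers: Set[str],
        noncarriers: Optional[Set[str]] = None,
    ) -> "TransmissionResult":
        """Single-origin descent analysis for a carrier set.

        Known non-carriers default to genotyped members not in
        ``carriers``.  A feasible origin is an individual (not a known
        non-carrier) from which every known carrier is reachable through
        parent-child links passing only through carriers or
        genotype-unknown members.  The reported introducer is the most
        recent (deepest) feasible origin; the transmission label is
        aggregated over affected carriers from the parent through whom the
        variant arrives.
        """
        carriers = set(carriers)
        for c in carriers:
            self.individual(c)
        if noncarriers is None:
            noncarriers = {i for i in self.genotyped_ids()} - carriers
        noncarriers = set(noncarriers) - carriers
        allowed = set(self.members) - noncarriers

        def reach_down(x: str) -> Set[str]:
            seen = {x}
            stack = [x]
            while stack:
                for c in self._children[stack.pop()]:
                    if c in allowed and c not in seen:
                        seen.add(c)
                        stack.append(c)
            return seen

        feasible = []
        for x in sorted(allowed):
            if carriers <= reach_down(x):
                feasible.append(x)
        if not carriers or not feasible:
            return TransmissionResult(
                label="undetermined",
                introducers=set(),
                consistent=False,
                diagnostics={"feasible_origins": []},
            )
        feasible.sort(key=lambda x: (-self._depth[x], x))
        introducer = feasible[0]
        reach = reach_down(introducer)

        routes = {}
        ambiguous = False
        for a in sorted(carriers & set(self.affected_ids())):
            if a == introducer:
                continue
            m = self.members[a]
            feasible_parents = []
            for p, side in ((m.mother, "maternal"), (m.father, "paternal")):
                if p is not None and p in allowed and p in reach:
                    feasible_parents.append(side)
            if len(feasible_parents) == 1:
                routes[a] = feasible_parents[0]
            else:
                routes[a] = "ambiguous"
                ambiguous = True
        sides = set(routes.values())
        if ambiguous or not routes:
            label = "undetermined"
        elif sides == {"maternal"}:
            label = "maternal"
        elif sides == {"paternal"}:
            label = "paternal"
        else:
            label = "both"
        return TransmissionResult(
            label=label,
            introducers={introducer},
            consistent=True,
            diagnostics={"feasible_origins": feasible, "routes": routes},
        )


@dataclass
class TransmissionResult:
    label: str
    introducers: Set[str]
    consistent: bool
    diagnostics: dict = field(default_factory=dict)
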