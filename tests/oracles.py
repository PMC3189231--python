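"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: kinship by
exhaustive ancestral-path counting, Fisher p-values by exact-fraction
enumeration over the hypergeometric support, overlaps by position
counting.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import List, Tuple

import numpy as np

from pedcnvseg.core import GenomicInterval
from pedcnvseg.pedigree import AFFECTED, UNAFFECTED, Individual, Pedigree


# ---------------------------------------------------------------------------
# overlap oracle: count shared positions between first/last-probe spans
# ---------------------------------------------------------------------------


def overlap_by_counting(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    # positions strictly between start and end plus the end boundary:
    # length end-start counts unit steps start->end
    steps_a = set(range(a.start, a.end))
    steps_b = set(range(b.start, b.end))
    return len(steps_a & steps_b)


# ---------------------------------------------------------------------------
# kinship oracle: path counting over all ancestral lineage paths
# ---------------------------------------------------------------------------


def _paths_up(ped: Pedigree, i: str):
    """All ancestral lineage paths from i: (ancestor, length, node set)."""
    out = [(i, 0, frozenset([i]))]
    m = ped.members[i]
    for p in (m.father, m.mother):
        if p is not None:
            for (a, d, s) in _paths_up(ped, p):
                out.append((a, d + 1, s | {i}))
    return out


def kinship_by_path_counting(ped: Pedigree, i: str, j: str) -> Fraction:
    if i == j:
        m = ped.members[i]
        if m.is_founder:
            return Fraction(1, 2)
        return Fraction(1, 2) * (1 + kinship_by_path_counting(ped, m.father, m.mother))
    total = Fraction(0)
    for (a, di, si) in _paths_up(ped, i):
        for (b, dj, sj) in _paths_up(ped, j):
            if a == b and si & sj == {a}:
                m = ped.members[a]
                if m.is_founder:
                    inbreeding = Fraction(0)
                else:
                    inbreeding = kinship_by_path_counting(ped, m.father, m.mother)
                total += Fraction(1, 2) ** (di + dj + 1) * (1 + inbreeding)
    return total


def random_pedigree(rng: np.random.Generator, max_generations: int = 5) -> Pedigree:
    """Random non-inbred pedigree: couples of founders marry in fresh
    founders each generation; some members affected."""
    members: List[Individual] = [
        Individual("f1", sex="1"),
        Individual("f2", sex="2"),
    ]
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"i{counter[0]}"

    frontier: List[Tuple[str, str]] = [("f1", "f2")]
    for gen in range(max_generations - 1):
        next_frontier = []
        for father, mother in frontier:
            for _ in range(int(rng.integers(1, 4))):
                child = Individual(
                    new_id(), father=father, mother=mother,
                    sex=str(int(rng.integers(1, 3))),
                    affection=AFFECTED if rng.random() < 0.3 else UNAFFECTED,
                    dna_available=bool(rng.random() < 0.8),
                )
                members.append(child)
                if gen < max_generations - 2 and rng.random() < 0.6:
                    spouse = Individual(
                        new_id(), sex="2" if child.sex == "1" else "1",
                        affection=UNAFFECTED, dna_available=True,
                    )
                    members.append(spouse)
                    couple = (
                        (child.iid, spouse.iid) if child.sex == "1"
                        else (spouse.iid, child.iid)
                    )
                    next_frontier.append(couple)
        frontier = next_frontier
        if not frontier:
            break
    return Pedigree("RAND", members)


# ---------------------------------------------------------------------------
# Fisher oracle: exact-fraction enumeration with fixed margins
# ---------------------------------------------------------------------------


def assert_fisher_matches_enumeration(nmax: int = 40) -> int:
    """Full scan of every 2x2 table with total <= nmax against the exact
    fraction oracle (margin-grouped).  Returns the number of tables checked."""
    from pedcnvseg.stats import ContingencyTable2x2, fisher_exact_two_sided

    checked = 0
    for total in range(1, nmax + 1):
        for r1 in range(total + 1):
            for c1 in range(total + 1):
                lo, hi = max(0, r1 + c1 - total), min(r1, c1)
                weights = {
                    k: math.comb(r1, k) * math.comb(total - r1, c1 - k)
                    for k in range(lo, hi + 1)
                }
                wsum = sum(weights.values())
                for a in range(lo, hi + 1):
                    tab = ContingencyTable2x2(a, r1 - a, c1 - a, total - r1 - c1 + a)
                    p = fisher_exact_two_sided(tab)
                    exact = Fraction(
                        sum(w for w in weights.values() if w <= weights[a]), wsum
                    )
                    assert math.isclose(p, float(exact), rel_tol=1e-7), (
                        a, r1 - a, c1 - a, total - r1 - c1 + a,
                    )
                    checked += 1
    return checked


def assert_kinship_matches_path_counting(
    n_pedigrees: int = 200, seed: int = 20260929, max_pairs: int = 40
) -> None:
    import itertools

    rng = np.random.default_rng(seed)
    for _ in range(n_pedigrees):
        ped = random_pedigree(rng, max_generations=5)
        ids = sorted(ped.members)
        pairs = list(itertools.combinations(ids, 2))
        if len(pairs) > max_pairs:
            idx = rng.choice(len(pairs), size=max_pairs, replace=False)
            pairs = [pairs[i] for i in idx]
        for i, j in pairs:
            assert ped.kinship(i, j) == kinship_by_path_counting(ped, i, j)


def fisher_p_by_enumeration(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided point-probability-sum p as an exact fraction."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return Fraction(1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    weights = {
        k: math.comb(r1, k) * math.comb(n - r1, c1 - k) for k in range(lo, hi + 1)
    }
    total = sum(weights.values())
    w_obs = weights[a]
    return Fraction(sum(w for w in weights.values() if w <= w_obs), total)
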