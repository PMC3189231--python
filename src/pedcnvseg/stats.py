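"""Exact 2x2 contingency statistics, rank-sum comparison and
carrier-frequency arithmetic.

The two-sided Fisher p-value follows the point-probability summation
convention: with all margins fixed, sum the hypergeometric point
probabilities of every table no more probable than the observed one
(within relative tolerance 1e-7).  Under this convention the 2x2 table
[[12, 8], [6, 14]] gives p = 0.111 to three decimals.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from scipy import stats as sps

from .io import round_half_up
from .pedigree import AFFECTED, Pedigree

logger = logging.getLogger(__name__)

_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts with rows = carrier status, columns = diagnosis status."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count in 2x2 table")
        if self.total == 0:
            raise ValueError("empty 2x2 table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by point-probability summation.

    Margins fixed; p = sum of P(tables) with point probability <= that of
    the observed table (relative tolerance 1e-7).  Any zero margin makes
    every table equally (un)informative: p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + _REL_TOL)].sum())
    return min(p, 1.0)


def _h_statistic(groups: Sequence[Sequence[float]]) -> float:
    """Tie-corrected Kruskal-Wallis H from mid-ranks (used for the exact
    permutation route; the chi-square route delegates to scipy)."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    offset = 0
    h = 0.0
    for g in groups:
        k = len(g)
        r = ranks[offset:offset + k]
        h += r.sum() ** 2 / k
        offset += k
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - ((counts ** 3 - counts).sum()) / (n ** 3 - n)
    if tie == 0:
        return 0.0
    return h / tie


def kruskal_wallis(
    groups: Sequence[Sequence[float]], exact: bool = False
) -> Tuple[float, float]:
    """Kruskal-Wallis rank-sum test over >= 2 groups of per-sample counts.

    Returns (H, p).  H carries the tie correction
    H' = H / (1 - sum(t^3 - t) / (N^3 - N)).  The p-value uses the
    chi-square approximation with k-1 degrees of freedom, or, with
    ``exact=True`` and pooled N <= 10, full permutation enumeration.
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    for g in groups:
        if len(g) == 0:
            raise ValueError("empty group in kruskal_wallis")
    pooled = [x for g in groups for x in g]
    if len(pooled) < 3:
        raise ValueError("kruskal_wallis needs total N >= 3")
    if len(set(pooled)) == 1:
        return 0.0, 1.0
    if exact:
        if len(pooled) > 10:
            raise ValueError("exact permutation limited to N <= 10")
        h_obs = _h_statistic(groups)
        sizes = [len(g) for g in groups]
        count = 0
        total = 0
        for perm in itertools.permutations(pooled):
            regrouped = []
            off = 0
            for k in sizes:
                regrouped.append(perm[off:off + k])
                off += k
            total += 1
            if _h_statistic(regrouped) >= h_obs - 1e-12:
                count += 1
        return h_obs, count / total
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


@dataclass(frozen=True)
class CarrierFrequency:
    """Exact carrier fraction plus its 3-decimal display value.

    The exact fraction is what threshold comparisons use; the half-up
    rounded value is display-only.
    """

    carriers: int
    cohort_size: int

    def __post_init__(self) -> None:
        if self.cohort_size <= 0:
            raise ValueError("cohort size must be positive")
        if not 0 <= self.carriers <= self.cohort_size:
            raise ValueError("carrier count outside [0, cohort size]")

    @property
    def exact(self) -> Fraction:
        return Fraction(self.carriers, self.cohort_size)

    @property
    def display(self) -> float:
        return round_half_up(self.exact, 3)


def carrier_frequency(carriers: int, n: int) -> CarrierFrequency:
    return CarrierFrequency(carriers, n)


def carrier_spouse_comparison(
    peds: Dict[str, Pedigree],
    candidates: Sequence,
    clinical: Dict[str, List[str]],
) -> Tuple[ContingencyTable2x2, float, Dict[str, object]]:
    """Compare diagnoses of unaffected CNV carriers against their
    non-carrier spouses.

    Carriers are pooled over all retained candidates, counted once per
    individual; a pair is a carrier plus a co-parent spouse who carries no
    candidate CNV of the family (carrier-carrier couples are excluded and
    logged).  The 2x2 rows are carrier / spouse, columns any-diagnosis /
    none; p is the two-sided Fisher exact p.
    """
    carriers_by_family: Dict[str, Set[str]] = {}
    for cand in candidates:
        if cand.verdict != "retained":
            continue
        carriers_by_family.setdefault(cand.family_id, set()).update(cand.carriers)

    pairs: List[Tuple[str, str]] = []
    excluded: List[Tuple[str, str]] = []
    seen_carriers: Set[str] = set()
    seen_spouses: Set[str] = set()
    for fam in sorted(carriers_by_family):
        ped = peds[fam]
        fam_carriers = carriers_by_family[fam]
        for iid in sorted(fam_carriers):
            m = ped.individual(iid)
            if m.affection == AFFECTED:
                continue  # the comparison is among members without an ASD diagnosis
            for spouse in ped.spouses_of(iid):
                if spouse in fam_carriers:
                    excluded.append((iid, spouse))
                    logger.info(
                        "family %s: spouse %s of carrier %s also carries; pair excluded",
                        fam, spouse, iid,
                    )
                    continue
                if iid not in seen_carriers and spouse not in seen_spouses:
                    pairs.append((iid, spouse))
                    seen_carriers.add(iid)
                    seen_spouses.add(spouse)
    if not pairs:
        raise ValueError("no comparable carrier-spouse pairs")

    def diagnosed(iid: str) -> bool:
        return bool(clinical.get(iid))

    a = sum(1 for c, _ in pairs if diagnosed(c))
    b = len(pairs) - a
    c = sum(1 for _, s in pairs if diagnosed(s))
    d = len(pairs) - c
    table = ContingencyTable2x2(a, b, c, d)
    p = fisher_exact_two_sided(table)
    return table, p, {"pairs": pairs, "excluded_pairs": excluded}
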