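"""Core domain types: genomic intervals, CNV calls and candidate loci.

Coordinate convention
---------------------
CNV boundaries on SNP arrays are the positions of the first and last
supporting probe.  An interval's length is therefore defined as
``end - start``: the span between the outermost probes, not a count of
bases in a half-open window.  BED input (0-based, half-open) is converted
on ingest so that ``start`` is the first covered position and ``end`` the
last (see :mod:`pedcnvseg.io`).

Copy-number semantics
---------------------
Array CNV callers emit only non-diploid segments, so copy number 2 is not
a representable call: absence of a call means diploid.  Copy numbers 0 and
1 are deletions, 3 and 4 duplications.

Two CNV records are considered *the same CNV* when their types match
(del vs del, dup vs dup) and they overlap reciprocally by at least a set
fraction (default 50%) of each record's length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

AUTOSOMES = frozenset(str(i) for i in range(1, 23))

DELETION = "del"
DUPLICATION = "dup"


def normalize_chrom(label: str) -> str:
    """Strip a ``chr`` prefix (any case) and upper-case the remainder."""
    s = str(label).strip()
    if s[:3].lower() == "chr":
        s = s[3:]
    return s.upper()


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome span between a first and a last probe position."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 0:
            raise ValueError(f"negative start position: {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end < start for {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_autosomal(self) -> bool:
        return self.chrom in AUTOSOMES

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"chr{self.chrom}:{self.start}-{self.end}"


def interval_length(iv: GenomicInterval) -> int:
    """Estimated length in bp: the span between first and last probe."""
    return iv.end - iv.start


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length of the overlap of two intervals (0 if disjoint). Symmetric."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def intersect_all(intervals: Sequence[GenomicInterval]) -> Optional[GenomicInterval]:
    """Common intersection of intervals on one chromosome.

    Returns ``None`` when the intersection is empty (zero or negative
    span).  Mixed chromosomes are a caller error.
    """
    if not intervals:
        raise ValueError("intersect_all requires a non-empty interval list")
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValueError(f"intervals span multiple chromosomes: {sorted(chroms)}")
    start = max(iv.start for iv in intervals)
    end = min(iv.end for iv in intervals)
    if end <= start:
        return None
    return GenomicInterval(intervals[0].chrom, start, end)


def same_locus(
    iv_a: GenomicInterval,
    type_a: str,
    iv_b: GenomicInterval,
    type_b: str,
    fraction: float = 0.5,
    mode: str = "reciprocal",
) -> bool:
    """Type-matched overlap test between two CNV loci.

    ``mode='reciprocal'`` (default) requires the shared span to cover at
    least ``fraction`` of *both* lengths; ``mode='either'`` of at least
    one.  Zero-length operands are degenerate and rejected.
    """
    if type_a != type_b:
        return False
    la, lb = iv_a.length, iv_b.length
    if la == 0 or lb == 0:
        raise ValueError("zero-length interval in CNV comparison")
    ov = overlap_bp(iv_a, iv_b)
    if ov == 0:
        return False
    hits_a = ov >= fraction * la
    hits_b = ov >= fraction * lb
    if mode == "reciprocal":
        return hits_a and hits_b
    if mode == "either":
        return hits_a or hits_b
    raise ValueError(f"unknown overlap mode: {mode!r}")


def is_same_cnv(a, b, fraction: float = 0.5, mode: str = "reciprocal") -> bool:
    """Whether two CNV records (call, candidate or population record)
    describe the same CNV: matching type and reciprocal overlap of at
    least ``fraction`` of both lengths."""
    return same_locus(a.interval, a.cnv_type, b.interval, b.cnv_type, fraction, mode)


@dataclass(frozen=True)
class CNVCall:
    """A per-sample non-diploid copy-number segment."""

    sample_id: str
    interval: GenomicInterval
    copy_number: int
    num_snps: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.copy_number == 2:
            raise ValueError("copy number 2 is diploid and not a call")
        if self.copy_number not in (0, 1, 3, 4):
            raise ValueError(f"unsupported copy number: {self.copy_number}")
        if self.num_snps < 1:
            raise ValueError("num_snps must be positive")

    @property
    def cnv_type(self) -> str:
        return DELETION if self.copy_number < 2 else DUPLICATION


@dataclass
class GeneContext:
    """Gene annotation attached to a candidate locus.

    ``relation`` is one of ``whole-gene`` (gene contained in the CNV),
    ``exonic-portion`` (CNV covers at least one exon but not the whole
    gene), ``intronic`` (CNV inside the gene, no exon touched),
    ``partial`` (overlaps the gene edge without covering an exon) or
    ``nearest`` (no overlap; ``distance_bp``/``direction`` filled in,
    direction relative to the gene's strand).
    """

    gene: str
    relation: str
    distance_bp: int = 0
    direction: str = ""


@dataclass
class CandidateCNV:
    """A family-level CNV shared by every genotyped affected member."""

    family_id: str
    interval: GenomicInterval
    cnv_type: str
    affected_carriers: list = field(default_factory=list)
    unaffected_blood_carriers: list = field(default_factory=list)
    married_in_carriers: list = field(default_factory=list)
    control_frequency_by_ancestry: dict = field(default_factory=dict)
    control_carrier_counts: dict = field(default_factory=dict)
    dgv_count: int = 0
    literature_overlap: str = "none"
    priority_tier: Optional[int] = None
    transmission: str = "undetermined"
    verdict: str = "candidate"
    reason: str = ""
    genes: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    @property
    def carriers(self) -> list:
        return (
            list(self.affected_carriers)
            + list(self.unaffected_blood_carriers)
            + list(self.married_in_carriers)
        )

    def matched_frequency(self, ancestry: str) -> Fraction:
        return self.control_frequency_by_ancestry.get(ancestry, Fraction(0))
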