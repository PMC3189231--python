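"""Readers and writers for every external file the pipeline touches.

Formats
-------
* PennCNV-style call files: one call per line, token-based
  (``chr<k>:<start>-<end>``, ``numsnp=<n>``, ``state<s>,cn=<c>``, a sample
  identifier token, optional ``length=``/``conf=``/``startsnp=``/... pairs).
  Any ``length=`` token is checked against the recomputed span, never
  trusted.
* Pre-makeped PED: whitespace-delimited ``family individual father mother
  sex phenotype`` with two optional extra columns, DNA availability (0/1)
  and ancestry label.  Phenotype 2 = affected, 1 = unaffected, 0/-9 =
  unknown.
* Population CNV tables (controls, DGV-like): TSV with columns
  ``chrom start end type cohort ancestry sample_id``.
* BED3+ for literature regions and BED12 for gene models; BED is 0-based
  half-open and is converted on ingest to the internal first/last-probe
  convention (start+1, end).
* Candidate report: TSV or JSON, deletions before duplications then by
  chromosome and start, frequencies printed half-up to 3 decimals with
  bracketed per-cohort carrier counts ("0.012 [8/1]").
* Run configuration: YAML.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import yaml
from intervaltree import IntervalTree

from .core import (
    CNVCall,
    CandidateCNV,
    GenomicInterval,
    interval_length,
    same_locus,
)
from .pedigree import AFFECTED, UNAFFECTED, UNKNOWN, Individual, Pedigree

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class QCThresholds:
    sdlrr_max: float = 0.4
    max_cnvs: int = 300
    min_call_rate: float = 0.95
    min_snps: int = 3
    review_sdlrr: Tuple[float, float] = (0.3, 0.4)   # strict bounds
    review_cnvs: Tuple[int, int] = (100, 300)        # inclusive bounds


@dataclass
class RunConfig:
    """Pipeline configuration with the study's defaults."""

    frequency_threshold: float = 0.015
    overlap_fraction: float = 0.5
    overlap_mode: str = "reciprocal"
    qc: QCThresholds = field(default_factory=QCThresholds)
    strict_qc: bool = False
    require_single_origin: bool = True
    seed: int = 0
    default_ancestry: str = "EUR"
    ancestry_by_family: Dict[str, str] = field(default_factory=dict)
    cohort_size_by_ancestry: Dict[str, int] = field(
        default_factory=lambda: {"EUR": 727, "AA": 111}
    )

    def __post_init__(self) -> None:
        for name, val in (
            ("frequency_threshold", self.frequency_threshold),
            ("overlap_fraction", self.overlap_fraction),
        ):
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if self.overlap_mode not in ("reciprocal", "either"):
            raise ValueError(f"unknown overlap_mode {self.overlap_mode!r}")

    def family_ancestry(self, family_id: str) -> str:
        return self.ancestry_by_family.get(family_id, self.default_ancestry)


def read_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    qc_raw = raw.pop("qc", {})
    qc = QCThresholds(**{k: tuple(v) if isinstance(v, list) else v for k, v in qc_raw.items()})
    return RunConfig(qc=qc, **raw)


def write_config(cfg: RunConfig, path) -> None:
    data = asdict(cfg)
    data["qc"]["review_sdlrr"] = list(data["qc"]["review_sdlrr"])
    data["qc"]["review_cnvs"] = list(data["qc"]["review_cnvs"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# PennCNV-style call files
# ---------------------------------------------------------------------------

_REGION_RE = re.compile(r"^(?:chr)?([0-9XYMTxymt]+):([\d,]+)-([\d,]+)$")


def read_penncnv_calls(path) -> List[CNVCall]:
    """Parse a PennCNV-style text call file (token-based).

    Every line is consumed, skipped-with-warning, or raises with its line
    number.  cn=2 records and malformed region tokens are errors.
    """
    calls: List[CNVCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            region = None
            kv: Dict[str, str] = {}
            others: List[str] = []
            for tok in tokens:
                m = _REGION_RE.match(tok)
                if m and region is None:
                    region = m
                    continue
                if "=" in tok:
                    key, _, val = tok.partition("=")
                    # "state2,cn=1" -> state token carries the cn pair
                    if key.startswith("state") and "," in key:
                        state, _, cnkey = key.partition(",")
                        kv["state"] = state[5:]
                        kv[cnkey] = val
                    else:
                        kv[key] = val
                else:
                    others.append(tok)
            if region is None:
                raise ParseError(f"{path}:{lineno}: no region token in line: {line!r}")
            if "cn" not in kv:
                raise ParseError(f"{path}:{lineno}: no cn= token in line: {line!r}")
            chrom = region.group(1)
            start = int(region.group(2).replace(",", ""))
            end = int(region.group(3).replace(",", ""))
            iv = GenomicInterval(chrom, start, end)
            cn = int(kv["cn"])
            if cn == 2:
                raise ParseError(f"{path}:{lineno}: cn=2 is diploid, not a call")
            numsnp = int(kv.get("numsnp", kv.get("snp", "0")).replace(",", ""))
            if numsnp < 1:
                raise ParseError(f"{path}:{lineno}: missing or invalid numsnp token")
            if "length" in kv:
                stated = int(kv["length"].replace(",", ""))
                if abs(stated - interval_length(iv)) > 1:
                    logger.warning(
                        "%s:%d: stated length %d differs from recomputed %d; "
                        "length is recomputed from boundaries",
                        path, lineno, stated, interval_length(iv),
                    )
            if not others:
                raise ParseError(f"{path}:{lineno}: no sample identifier token")
            sample = others[0]
            if sample.endswith(".txt"):
                sample = sample[:-4]
            calls.append(
                CNVCall(
                    sample_id=sample,
                    interval=iv,
                    copy_number=cn,
                    num_snps=numsnp,
                    source=kv.get("source", ""),
                )
            )
    return calls


def write_penncnv_calls(calls: Sequence[CNVCall], path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            state = {0: 1, 1: 2, 3: 5, 4: 6}[c.copy_number]
            fh.write(
                f"chr{c.interval.chrom}:{c.interval.start}-{c.interval.end}\t"
                f"numsnp={c.num_snps}\tlength={interval_length(c.interval):,}\t"
                f"state{state},cn={c.copy_number}\t{c.sample_id}\n"
            )


# ---------------------------------------------------------------------------
# PED files
# ---------------------------------------------------------------------------

_PHENO = {"2": AFFECTED, "1": UNAFFECTED, "0": UNKNOWN, "-9": UNKNOWN}
_PHENO_OUT = {AFFECTED: "2", UNAFFECTED: "1", UNKNOWN: "0"}


def read_ped(path) -> Dict[str, Pedigree]:
    """Read a 6+-column PED file into one Pedigree per family.

    Optional column 7 is DNA availability (0/1), column 8 an ancestry
    label (family-level, recorded on the returned pedigree as
    ``ancestry``)."""
    rows: Dict[str, List[Individual]] = {}
    ancestry: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 columns, got {len(f)}")
            fam, iid, father, mother, sex, pheno = f[:6]
            if pheno not in _PHENO:
                raise ParseError(f"{path}:{lineno}: bad phenotype code {pheno!r}")
            dna = bool(int(f[6])) if len(f) > 6 else True
            if len(f) > 7:
                ancestry[fam] = f[7]
            rows.setdefault(fam, []).append(
                Individual(
                    iid=iid,
                    father=None if father == "0" else father,
                    mother=None if mother == "0" else mother,
                    sex=sex,
                    affection=_PHENO[pheno],
                    dna_available=dna,
                )
            )
    peds: Dict[str, Pedigree] = {}
    for fam, members in rows.items():
        ped = Pedigree(fam, members)
        ped.ancestry = ancestry.get(fam)  # type: ignore[attr-defined]
        peds[fam] = ped
    return peds


def write_ped(peds: Dict[str, Pedigree], path) -> None:
    with open(path, "w") as fh:
        for fam in sorted(peds):
            ped = peds[fam]
            anc = getattr(ped, "ancestry", None)
            for iid in sorted(ped.members):
                m = ped.members[iid]
                cols = [
                    fam, iid, m.father or "0", m.mother or "0", m.sex,
                    _PHENO_OUT[m.affection], "1" if m.dna_available else "0",
                ]
                if anc is not None:
                    cols.append(anc)
                fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# QC metrics and clinical sidecars
# ---------------------------------------------------------------------------


def read_qc_metrics(path):
    """TSV sidecar with header sample_id, sdlrr, n_cnvs, call_rate."""
    from .qc import SampleQCMetrics

    out = {}
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for name in ("sample_id", "sdlrr", "n_cnvs", "call_rate"):
            if name not in idx:
                raise ParseError(f"{path}: missing QC column {name!r}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            m = SampleQCMetrics(
                sample_id=f[idx["sample_id"]],
                sdlrr=float(f[idx["sdlrr"]]),
                n_cnvs=int(f[idx["n_cnvs"]]),
                call_rate=float(f[idx["call_rate"]]),
            )
            out[m.sample_id] = m
    return out


def write_qc_metrics(metrics, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tsdlrr\tn_cnvs\tcall_rate\n")
        for m in sorted(metrics.values(), key=lambda m: m.sample_id):
            fh.write(f"{m.sample_id}\t{m.sdlrr}\t{m.n_cnvs}\t{m.call_rate}\n")


def read_clinical_sidecar(path) -> Dict[str, List[str]]:
    """TSV mapping individual id to comma-separated non-ASD diagnoses."""
    out: Dict[str, List[str]] = {}
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header[:2] != ["individual_id", "diagnoses"]:
            raise ParseError(f"{path}: expected columns individual_id, diagnoses")
        for line in fh:
            if not line.strip():
                continue
            iid, _, labels = line.rstrip("\n").partition("\t")
            out[iid] = [d for d in labels.split(",") if d]
    return out


def write_clinical_sidecar(diagnoses: Dict[str, List[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("individual_id\tdiagnoses\n")
        for iid in sorted(diagnoses):
            fh.write(f"{iid}\t{','.join(diagnoses[iid])}\n")


# ---------------------------------------------------------------------------
# population CNV tables
# ---------------------------------------------------------------------------

_TYPES = {"del", "dup"}


@dataclass(frozen=True)
class PopulationRecord:
    interval: GenomicInterval
    cnv_type: str
    cohort: str
    ancestry: str
    sample_id: str


class PopulationCNVTable:
    """Type-stratified interval store over control/DGV CNV records.

    Carrier counting is per distinct individual: a sample with two
    matching records counts once.
    """

    def __init__(
        self,
        records: Iterable[PopulationRecord],
        cohort_size_by_ancestry: Optional[Dict[str, int]] = None,
    ):
        self.records: List[PopulationRecord] = list(records)
        self.cohort_size_by_ancestry = dict(cohort_size_by_ancestry or {})
        self._trees: Dict[Tuple[str, str], IntervalTree] = {}
        for rec in self.records:
            key = (rec.interval.chrom, rec.cnv_type)
            tree = self._trees.setdefault(key, IntervalTree())
            # interval tree uses half-open [start, end); spans here are
            # first/last probe positions with positive length
            tree.addi(rec.interval.start, rec.interval.end, rec)

    def __len__(self) -> int:
        return len(self.records)

    def matching_records(
        self, interval: GenomicInterval, cnv_type: str,
        fraction: float = 0.5, mode: str = "reciprocal",
    ) -> List[PopulationRecord]:
        tree = self._trees.get((interval.chrom, cnv_type))
        if tree is None:
            return []
        hits = []
        for node in tree.overlap(interval.start, interval.end):
            rec = node.data
            if same_locus(interval, cnv_type, rec.interval, rec.cnv_type, fraction, mode):
                hits.append(rec)
        return hits

    def carrier_counts(
        self, interval: GenomicInterval, cnv_type: str,
        fraction: float = 0.5, mode: str = "reciprocal",
    ) -> Dict[str, Dict[str, int]]:
        """Distinct carriers by ancestry and cohort."""
        seen: Dict[str, Dict[str, set]] = {}
        counted: set = set()
        for rec in self.matching_records(interval, cnv_type, fraction, mode):
            if rec.sample_id in counted:
                continue
            counted.add(rec.sample_id)
            seen.setdefault(rec.ancestry, {}).setdefault(rec.cohort, set()).add(rec.sample_id)
        return {
            anc: {coh: len(ids) for coh, ids in cohorts.items()}
            for anc, cohorts in seen.items()
        }

    def carrier_frequency(
        self, interval: GenomicInterval, cnv_type: str, ancestry: str,
        fraction: float = 0.5, mode: str = "reciprocal",
    ) -> Fraction:
        if ancestry not in self.cohort_size_by_ancestry:
            raise KeyError(f"no cohort size known for ancestry {ancestry!r}")
        counts = self.carrier_counts(interval, cnv_type, fraction, mode).get(ancestry, {})
        return Fraction(sum(counts.values()), self.cohort_size_by_ancestry[ancestry])

    def total_carriers(
        self, interval: GenomicInterval, cnv_type: str,
        fraction: float = 0.5, mode: str = "reciprocal",
    ) -> int:
        return len({r.sample_id for r in self.matching_records(interval, cnv_type, fraction, mode)})


def read_population_table(
    path, cohort_size_by_ancestry: Optional[Dict[str, int]] = None
) -> PopulationCNVTable:
    """TSV with header chrom, start, end, type, cohort, ancestry, sample_id
    (the last three optional, defaulting to empty / 'NA' / a row id)."""
    records = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for name in ("chrom", "start", "end", "type"):
            if name not in idx:
                raise ParseError(f"{path}: missing population-table column {name!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            ctype = f[idx["type"]].lower()
            if ctype not in _TYPES:
                raise ParseError(f"{path}:{lineno}: unknown CNV type token {ctype!r}")
            records.append(
                PopulationRecord(
                    interval=GenomicInterval(
                        f[idx["chrom"]], int(f[idx["start"]]), int(f[idx["end"]])
                    ),
                    cnv_type=ctype,
                    cohort=f[idx["cohort"]] if "cohort" in idx else "",
                    ancestry=f[idx["ancestry"]] if "ancestry" in idx else "NA",
                    sample_id=f[idx["sample_id"]] if "sample_id" in idx else f"row{lineno}",
                )
            )
    return PopulationCNVTable(records, cohort_size_by_ancestry)


def write_population_table(table: PopulationCNVTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\ttype\tcohort\tancestry\tsample_id\n")
        for r in table.records:
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"{r.cnv_type}\t{r.cohort}\t{r.ancestry}\t{r.sample_id}\n"
            )


# ---------------------------------------------------------------------------
# BED ingestion (0-based half-open -> first/last probe positions)
# ---------------------------------------------------------------------------


def _bed_to_interval(chrom: str, start: int, end: int) -> GenomicInterval:
    if end <= start:
        raise ParseError(f"empty BED interval {chrom}:{start}-{end}")
    return GenomicInterval(chrom, start + 1, end)


@dataclass
class LiteratureRegion:
    interval: GenomicInterval
    name: str = ""


def read_literature_bed(path) -> List[LiteratureRegion]:
    """BED3+ of previously reported disease-associated regions."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            out.append(
                LiteratureRegion(
                    interval=_bed_to_interval(f[0], int(f[1]), int(f[2])),
                    name=f[3] if len(f) > 3 else "",
                )
            )
    return out


@dataclass
class GeneModel:
    name: str
    strand: str
    interval: GenomicInterval
    exons: List[GenomicInterval] = field(default_factory=list)


def read_genes_bed(path) -> List[GeneModel]:
    """Gene models from BED12 (blocks = exons) or BED6 (single-exon)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: gene BED needs >= 6 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            gene = GeneModel(
                name=f[3], strand=f[5], interval=_bed_to_interval(chrom, start, end)
            )
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                for size, off in zip(sizes, offsets):
                    gene.exons.append(_bed_to_interval(chrom, start + off, start + off + size))
            else:
                gene.exons.append(gene.interval)
            out.append(gene)
    return out


# ---------------------------------------------------------------------------
# candidate report
# ---------------------------------------------------------------------------


def round_half_up(value: Fraction | float, decimals: int = 3) -> float:
    """Display rounding: half-up at ``decimals`` places."""
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(str(value))
    q = Decimal(1).scaleb(-decimals)
    return float(dec.quantize(q, rounding=ROUND_HALF_UP))


def format_frequency(freq: Fraction, counts: Dict[str, int], cohorts: Sequence[str]) -> str:
    """Render ``0.012 [8/1]`` style annotations (cohort order fixed)."""
    if freq == 0:
        head = "0"
    else:
        head = f"{round_half_up(freq, 3):.3f}"
    bracket = "/".join(str(counts.get(c, 0)) for c in cohorts)
    return f"{head} [{bracket}]" if cohorts else head


def _chrom_sort_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def sort_candidates(candidates: Sequence[CandidateCNV]) -> List[CandidateCNV]:
    """Deterministic report order: deletions before duplications, then by
    chromosome, then start."""
    return sorted(
        candidates,
        key=lambda c: (
            0 if c.cnv_type == "del" else 1,
            _chrom_sort_key(c.interval.chrom),
            c.interval.start,
            c.family_id,
        ),
    )


REPORT_COHORTS = ("HIHG", "NBC")


def candidate_row(c: CandidateCNV, ancestries: Sequence[str]) -> Dict[str, object]:
    row: Dict[str, object] = {
        "cnv_type": c.cnv_type,
        "chrom": c.interval.chrom,
        "start": c.interval.start,
        "end": c.interval.end,
        "length_bp": interval_length(c.interval),
        "family_id": c.family_id,
        "genes": ";".join(
            f"{g.gene}:{g.relation}" + (f":{g.distance_bp}{g.direction and ':' + g.direction}" if g.relation == "nearest" else "")
            for g in c.genes
        ),
        "affected_carriers": ",".join(c.affected_carriers),
        "unaffected_blood_carriers": ",".join(c.unaffected_blood_carriers),
        "married_in_carriers": ",".join(c.married_in_carriers),
    }
    for anc in ancestries:
        freq = c.control_frequency_by_ancestry.get(anc, Fraction(0))
        counts = c.control_carrier_counts.get(anc, {})
        row[f"freq_{anc}"] = format_frequency(freq, counts, REPORT_COHORTS)
    row.update(
        dgv_count=c.dgv_count,
        literature_overlap=c.literature_overlap,
        priority_tier="" if c.priority_tier is None else c.priority_tier,
        transmission=c.transmission,
        verdict=c.verdict,
        reason=c.reason,
    )
    return row


def write_candidate_report(
    candidates: Sequence[CandidateCNV], path, format: str = "tsv",
    ancestries: Sequence[str] = ("EUR", "AA"),
) -> None:
    rows = [candidate_row(c, ancestries) for c in sort_candidates(candidates)]
    header = list(
        candidate_row(CandidateCNV("", GenomicInterval("1", 1, 2), "del"), ancestries)
    )
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(str(row[h]) for h in header) + "\n")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_candidate_report(path) -> List[Dict[str, str]]:
    """Read a TSV report back as a list of row dicts (all values str)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        rows = []
        for line in fh:
            if not line.strip():
                continue
            rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    return rows
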