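"""Deterministic reference cohort: eleven extended families carrying the
twelve validated co-segregating CNVs (five deletions, seven duplications).

Each family uses a canonical first-cousin-pair topology (documented
simplification: the published drawn pedigrees are not machine-readable,
and the analysis surfaces — carrier counts, lengths, frequencies,
transmission labels — do not depend on the drawn topology).  Deletion
families transmit through two blood-line sisters, so the variants arrive
maternally; duplication families transmit through a brother and a sister,
so descent mixes maternal and paternal routes.  Family 17122 carries two
duplications (7p21.3 and 15q24.1) in the same four individuals.

The control table realizes the published per-cohort carrier counts over
the 727 European-ancestry and 111 African-American control totals, and
the DGV-like table realizes the published catalogue counts (">300"
realized as 301 records; the pipeline thresholds on presence, not
magnitude).  Gene models and literature regions are synthetic stand-ins
constructed so each locus reproduces its reported gene context
(intronic / whole-gene / exonic-portion / nearest-gene distance).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

from .core import CNVCall, GenomicInterval
from .io import (
    PopulationCNVTable,
    PopulationRecord,
    RunConfig,
    write_clinical_sidecar,
    write_config,
    write_ped,
    write_penncnv_calls,
    write_population_table,
    write_qc_metrics,
)
from .pedigree import Pedigree
from .qc import SampleQCMetrics
from .simulate import generate_pedigree

COHORT_SIZES = {"EUR": 727, "AA": 111}


@dataclass(frozen=True)
class ReferenceCNV:
    cytoband: str
    cnv_type: str
    chrom: str
    start: int
    end: int
    family: str
    eur_carriers: Tuple[int, int]   # (HIHG, NBC)
    aa_carriers: Tuple[int, int]
    dgv_count: int

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


#: The twelve validated co-segregating CNVs.
REFERENCE_CNVS: List[ReferenceCNV] = [
    ReferenceCNV("1p34.1", "del", "1", 45408389, 45411073, "17545", (8, 1), (3, 0), 4),
    ReferenceCNV("2p24.2-p24.1", "del", "2", 19065745, 19100096, "7745", (0, 0), (0, 0), 5),
    ReferenceCNV("6q11.1", "del", "6", 62507037, 62519883, "17342", (0, 0), (0, 0), 2),
    ReferenceCNV("12q24.32", "del", "12", 125875006, 125881162, "17678", (1, 4), (0, 0), 18),
    ReferenceCNV("13q31.1", "del", "13", 77912491, 77917728, "17142", (0, 0), (0, 0), 0),
    ReferenceCNV("3p26.3", "dup", "3", 57010, 103697, "37994", (2, 0), (0, 0), 5),
    ReferenceCNV("4p16.3", "dup", "4", 2704290, 2747426, "7663", (0, 0), (0, 0), 0),
    ReferenceCNV("7p21.3", "dup", "7", 8144894, 8497305, "17122", (0, 0), (0, 0), 0),
    ReferenceCNV("10p12.31", "dup", "10", 21727129, 21818381, "37232", (0, 0), (0, 0), 0),
    ReferenceCNV("10q23.32", "dup", "10", 93621936, 93730409, "37425", (0, 0), (0, 0), 0),
    ReferenceCNV("15q11.2", "dup", "15", 18411624, 18472812, "17668", (3, 0), (0, 1), 301),
    ReferenceCNV("15q24.1", "dup", "15", 72538187, 72549215, "17122", (0, 0), (0, 0), 0),
]

#: Families whose transmitting blood-line parent is DNA-unavailable
#: (genotype-unknown, permissive in descent paths), leaving 20 genotyped
#: unaffected carrier-spouse pairs across the cohort.
_UNTYPED_TRANSMITTER = {"17545": "b2", "17342": "b2"}

_DIAGNOSIS_LABELS = [
    "ADHD", "anxiety-disorder", "speech-disorder", "depression",
    "OCD", "bipolar-disorder", "ODD", "alcoholism",
]

# synthetic gene models: (name, chrom, strand, gene_start, gene_end, extra
# internal exons as (start, end) in first/last-probe coordinates); every
# gene also gets terminal exons at both ends
_SYNTHETIC_GENES = [
    ("ZSWIM5", "1", "+", 45330001, 45500000, []),
    ("OSR1", "2", "-", 19200001, 19250000, []),
    ("CHL1", "3", "+", 212697, 400000, []),
    ("TNIP2", "4", "-", 2710001, 2730000, []),
    ("ICA1", "7", "-", 8100001, 8300000, []),
    ("NXPH1", "7", "+", 8450001, 8800000, []),
    ("C10orf114", "10", "-", 21900001, 21950000, []),
    ("FGFBP3", "10", "-", 93650001, 93655000, []),
    ("BTAF1", "10", "+", 93700001, 93790000, []),
    ("KHDRBS2", "6", "-", 62400001, 62700000, []),
    ("LOC100128554", "12", "+", 125950001, 125970000, []),
    ("POU4F1", "13", "+", 78071228, 78076000, []),
    ("GOLGA6L6", "15", "+", 18500001, 18520000, []),
    ("UBL7", "15", "+", 72530001, 72560000, [(72540001, 72541000)]),
]

_LITERATURE_REGIONS = [
    ("7", 8144894, 8497305, "ASD_dup_7p21.3"),
    ("15", 72538187, 72549215, "ASD_dup_15q24.1"),
]


@dataclass
class FixtureData:
    peds: Dict[str, Pedigree]
    calls: List[CNVCall]
    qc_metrics: Dict[str, SampleQCMetrics]
    control_table: PopulationCNVTable
    dgv_table: PopulationCNVTable
    clinical: Dict[str, List[str]]
    config: RunConfig
    carrier_members: Dict[str, List[str]]  # family -> carrier member tags


def _family_carriers(fam: str) -> List[str]:
    """Member tags carrying the family's CNV: both probands and the
    genotyped transmitting blood-line parents."""
    tags = ["p1", "p2", "b1", "b2"]
    untyped = _UNTYPED_TRANSMITTER.get(fam)
    return [t for t in tags if t != untyped]


def build_fixture() -> FixtureData:
    peds: Dict[str, Pedigree] = {}
    calls: List[CNVCall] = []
    carrier_members: Dict[str, List[str]] = {}

    for fam in sorted({r.family for r in REFERENCE_CNVS}):
        rows = [r for r in REFERENCE_CNVS if r.family == fam]
        sex_mode = "female" if rows[0].cnv_type == "del" else "mixed"
        ped, _ = generate_pedigree("first_cousin_pair", fam, transmitting_sex=sex_mode)
        untyped = _UNTYPED_TRANSMITTER.get(fam)
        if untyped is not None:
            ped.members[f"{fam}_{untyped}"].dna_available = False
        peds[fam] = ped
        ped.ancestry = "EUR"  # type: ignore[attr-defined]
        carrier_members[fam] = _family_carriers(fam)
        for row in rows:
            cn = 1 if row.cnv_type == "del" else 3
            num_snps = max(5, (row.end - row.start) // 1000)
            for tag in carrier_members[fam]:
                calls.append(
                    CNVCall(f"{fam}_{tag}", row.interval, cn, num_snps, source="fixture")
                )

    n_calls: Dict[str, int] = {}
    for c in calls:
        n_calls[c.sample_id] = n_calls.get(c.sample_id, 0) + 1
    qc_metrics = {
        sid: SampleQCMetrics(sid, sdlrr=0.15, n_cnvs=n_calls.get(sid, 0), call_rate=0.99)
        for fam, ped in peds.items()
        for sid in ped.genotyped_ids()
    }

    control_records: List[PopulationRecord] = []
    dgv_records: List[PopulationRecord] = []
    for row in REFERENCE_CNVS:
        for anc, (hihg, nbc) in (("EUR", row.eur_carriers), ("AA", row.aa_carriers)):
            for cohort, n in (("HIHG", hihg), ("NBC", nbc)):
                for i in range(n):
                    control_records.append(
                        PopulationRecord(
                            row.interval, row.cnv_type, cohort, anc,
                            f"CTRL_{anc}_{cohort}_{row.cytoband}_{i:02d}",
                        )
                    )
        for i in range(row.dgv_count):
            dgv_records.append(
                PopulationRecord(
                    row.interval, row.cnv_type, "DGV", "NA",
                    f"DGV_{row.cytoband}_{i:03d}",
                )
            )

    # clinical sidecar: 12 of the 20 genotyped unaffected carriers and 6 of
    # their 20 non-carrier spouses have a psychiatric/developmental label
    carrier_ids: List[str] = []
    spouse_of: Dict[str, str] = {}
    for fam in sorted(peds):
        for tag in ("b1", "b2"):
            if tag in carrier_members[fam]:
                carrier_ids.append(f"{fam}_{tag}")
                spouse_of[f"{fam}_{tag}"] = f"{fam}_s{tag[1]}"
    clinical: Dict[str, List[str]] = {}
    for k, cid in enumerate(carrier_ids[:12]):
        clinical[cid] = [_DIAGNOSIS_LABELS[k % len(_DIAGNOSIS_LABELS)]]
    for k, cid in enumerate(carrier_ids[:6]):
        clinical[spouse_of[cid]] = [_DIAGNOSIS_LABELS[(k + 3) % len(_DIAGNOSIS_LABELS)]]

    config = RunConfig(
        ancestry_by_family={fam: "EUR" for fam in peds},
        cohort_size_by_ancestry=dict(COHORT_SIZES),
    )
    return FixtureData(
        peds=peds,
        calls=calls,
        qc_metrics=qc_metrics,
        control_table=PopulationCNVTable(control_records, dict(COHORT_SIZES)),
        dgv_table=PopulationCNVTable(dgv_records),
        clinical=clinical,
        config=config,
        carrier_members=carrier_members,
    )


def literature_regions():
    from .io import LiteratureRegion

    return [
        LiteratureRegion(GenomicInterval(c, s, e), name)
        for c, s, e, name in _LITERATURE_REGIONS
    ]


def gene_models():
    from .io import GeneModel

    genes = []
    for name, chrom, strand, gstart, gend, extra in _SYNTHETIC_GENES:
        iv = GenomicInterval(chrom, gstart, gend)
        exons = [
            GenomicInterval(chrom, gstart, min(gstart + 1999, gend)),
            GenomicInterval(chrom, max(gend - 1999, gstart), gend),
        ]
        exons += [GenomicInterval(chrom, s, e) for s, e in extra]
        genes.append(GeneModel(name=name, strand=strand, interval=iv, exons=exons))
    return genes


def _interval_to_bed(iv: GenomicInterval) -> Tuple[int, int]:
    # internal first/last-probe positions back to 0-based half-open
    return iv.start - 1, iv.end


def paper_fixture(out_dir=None) -> FixtureData:
    """Build the reference cohort and, if ``out_dir`` is given, write all
    pipeline input files (byte-deterministic)."""
    data = build_fixture()
    if out_dir is None:
        return data
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_ped(data.peds, out / "families.ped")
    write_penncnv_calls(
        sorted(data.calls, key=lambda c: (c.sample_id, c.interval.chrom, c.interval.start)),
        out / "calls.rawcnv",
    )
    write_qc_metrics(data.qc_metrics, out / "qc_metrics.tsv")
    write_population_table(data.control_table, out / "controls.tsv")
    write_population_table(data.dgv_table, out / "dgv.tsv")
    write_clinical_sidecar(data.clinical, out / "clinical.tsv")
    with open(out / "literature.bed", "w") as fh:
        for chrom, s, e, name in _LITERATURE_REGIONS:
            bs, be = _interval_to_bed(GenomicInterval(chrom, s, e))
            fh.write(f"{chrom}\t{bs}\t{be}\t{name}\n")
    with open(out / "genes.bed", "w") as fh:
        for g in gene_models():
            bs, be = _interval_to_bed(g.interval)
            starts = []
            sizes = []
            for exon in sorted(g.exons, key=lambda e: e.start):
                es, ee = _interval_to_bed(exon)
                starts.append(es - bs)
                sizes.append(ee - es)
            fh.write(
                f"{g.interval.chrom}\t{bs}\t{be}\t{g.name}\t0\t{g.strand}\t"
                f"{bs}\t{be}\t0\t{len(sizes)}\t"
                f"{','.join(map(str, sizes))}\t{','.join(map(str, starts))}\n"
            )
    write_config(data.config, out / "config.yaml")
    return data


def run_fixture_pipeline(out_dir=None):
    """Run the end-to-end pipeline on the reference cohort."""
    from .pipeline import run_pipeline

    data = paper_fixture(out_dir)
    result = run_pipeline(
        data.peds,
        data.calls,
        data.qc_metrics,
        data.control_table,
        data.dgv_table,
        data.config,
        literature_regions(),
        gene_models(),
    )
    if out_dir is not None:
        from .io import write_candidate_report

        out = Path(out_dir)
        write_candidate_report(result.retained, out / "candidates.tsv", "tsv", ("EUR", "AA"))
        write_candidate_report(result.retained, out / "candidates.json", "json", ("EUR", "AA"))
    return data, result
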