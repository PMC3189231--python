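"""Seeded generator of extended-family cohorts with planted risk CNVs.

The generator emulates the study design the analysis assumes: a set of
extended families ascertained for multiple affected cousins (default mix
28 families with two, 8 with three and 6 with four affected cousin-or-
more-distant relatives, 42 in all), a dominant risk CNV introduced by a
lineage founder and transmitted with incomplete penetrance, background
CNV polymorphisms segregating at their population frequencies, and a
pediatric control cohort (default 727 European-ancestry plus 111
African-American samples).

Gene dropping is Mendelian: founders receive alleles (by designation for
planted variants, by carrier frequency for background loci), each child
inherits one allele from each parent with probability allele-count/2, and
affection is assigned as penetrance for carriers and the phenocopy rate
for non-carriers.  Families are resampled until the ascertainment
condition (the required number of affected probands) holds.

Every planted and background variant is recorded in a truth log together
with its introducer, carrier set, transmission route and whether the
co-segregation screen is expected to retain it — the oracle for
end-to-end tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .core import CNVCall, GenomicInterval, interval_length
from .io import (
    PopulationCNVTable,
    PopulationRecord,
    RunConfig,
    write_ped,
    write_penncnv_calls,
    write_population_table,
    write_qc_metrics,
)
from .pedigree import AFFECTED, UNAFFECTED, UNKNOWN, Individual, Pedigree
from .qc import SampleQCMetrics

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# pedigree templates
# ---------------------------------------------------------------------------

TEMPLATES = (
    "avuncular_pair",
    "first_cousin_pair",
    "second_cousin_pair",
    "three_affected",
    "four_affected",
)

_STRUCTURE_BY_COUNT = {2: "first_cousin_pair", 3: "three_affected", 4: "four_affected"}


def generate_pedigree(
    structure: str | int,
    family_id: str,
    transmitting_sex: str = "mixed",
) -> Tuple[Pedigree, List[str]]:
    """Build a canonical extended-family pedigree.

    Returns the pedigree and the proband slots (the affected-cousin
    generation, pre-marked affected).  ``transmitting_sex`` controls the
    sex of the blood-line parents: "female" (all sisters, so any variant
    from the founders reaches the probands maternally) or "mixed"
    (alternating, so descent mixes maternal and paternal routes).
    Founders are DNA-unavailable, all descendants and spouses typed,
    mirroring real extended pedigrees where the top generation is rarely
    available.
    """
    if isinstance(structure, int):
        try:
            structure = _STRUCTURE_BY_COUNT[structure]
        except KeyError:
            raise ValueError(f"no template for {structure} affected cousins")
    if structure not in TEMPLATES:
        raise ValueError(f"unknown pedigree template {structure!r}")

    def iid(tag: str) -> str:
        return f"{family_id}_{tag}"

    members: List[Individual] = [
        Individual(iid("f1"), sex="1", affection=UNKNOWN, dna_available=False),
        Individual(iid("f2"), sex="2", affection=UNKNOWN, dna_available=False),
    ]
    probands: List[str] = []

    def blood_sex(i: int) -> str:
        if transmitting_sex == "female":
            return "2"
        if transmitting_sex == "male":
            return "1"
        return "1" if i % 2 == 1 else "2"

    def add_branch(i: int, generations: int) -> None:
        """A blood child of the founders, a married-in spouse, and a
        descendant chain ending in one proband ``generations`` below the
        blood child."""
        bsex = blood_sex(i)
        blood = Individual(
            iid(f"b{i}"), father=iid("f1"), mother=iid("f2"), sex=bsex,
            affection=UNAFFECTED, dna_available=True,
        )
        spouse = Individual(
            iid(f"s{i}"), sex="1" if bsex == "2" else "2",
            affection=UNAFFECTED, dna_available=True,
        )
        members.extend([blood, spouse])
        parent_f = blood if bsex == "1" else spouse
        parent_m = blood if bsex == "2" else spouse
        if generations == 1:
            members.append(
                Individual(
                    iid(f"p{i}"), father=parent_f.iid, mother=parent_m.iid,
                    sex="1", affection=AFFECTED, dna_available=True,
                )
            )
            probands.append(iid(f"p{i}"))
        else:
            mid = Individual(
                iid(f"m{i}"), father=parent_f.iid, mother=parent_m.iid,
                sex=bsex, affection=UNAFFECTED, dna_available=True,
            )
            mid_sp = Individual(
                iid(f"ms{i}"), sex="1" if bsex == "2" else "2",
                affection=UNAFFECTED, dna_available=True,
            )
            members.extend([mid, mid_sp])
            members.append(
                Individual(
                    iid(f"p{i}"),
                    father=mid.iid if bsex == "1" else mid_sp.iid,
                    mother=mid.iid if bsex == "2" else mid_sp.iid,
                    sex="1", affection=AFFECTED, dna_available=True,
                )
            )
            probands.append(iid(f"p{i}"))

    if structure == "avuncular_pair":
        # affected uncle (a blood child of the founders) plus affected nephew
        uncle = Individual(
            iid("b1"), father=iid("f1"), mother=iid("f2"), sex="1",
            affection=AFFECTED, dna_available=True,
        )
        members.append(uncle)
        probands.append(uncle.iid)
        add_branch(2, generations=1)
    elif structure == "first_cousin_pair":
        add_branch(1, 1)
        add_branch(2, 1)
    elif structure == "second_cousin_pair":
        add_branch(1, 2)
        add_branch(2, 2)
    elif structure == "three_affected":
        for i in (1, 2, 3):
            add_branch(i, 1)
    elif structure == "four_affected":
        for i in (1, 2, 3, 4):
            add_branch(i, 1)
    ped = Pedigree(family_id, members)
    return ped, probands


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------


@dataclass
class GeneDropResult:
    alleles: Dict[str, int]          # 0 / 1 / 2 risk alleles per member
    affection: Dict[str, str]
    n_resamples: int

    @property
    def carriers(self) -> Set[str]:
        return {i for i, a in self.alleles.items() if a > 0}


def gene_drop(
    ped: Pedigree,
    rng: np.random.Generator,
    introducer: Optional[str] = None,
    carrier_frequency: Optional[float] = None,
    penetrance: float = 1.0,
    phenocopy: float = 0.0,
    probands: Optional[Sequence[str]] = None,
    require_affected: Optional[int] = None,
    hom_rate: float = 0.0,
    max_resamples: int = 100_000,
) -> GeneDropResult:
    """Drop one locus through a pedigree.

    Founder carrier status comes from ``introducer`` (designated, one
    heterozygous copy) or ``carrier_frequency`` (each founder carries
    with that probability; homozygous with ``hom_rate`` given carrier).
    When ``require_affected`` is set, the family is resampled until at
    least that many ``probands`` are affected.
    """
    if (introducer is None) == (carrier_frequency is None):
        raise ValueError("specify exactly one of introducer / carrier_frequency")
    if carrier_frequency is not None and not 0 <= carrier_frequency <= 1:
        raise ValueError(f"carrier frequency outside [0, 1]: {carrier_frequency}")
    for p in (penetrance, phenocopy):
        if not 0 <= p <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
    if introducer is not None:
        ped.individual(introducer)
    order = sorted(ped.members, key=lambda i: (ped.depth(i), i))
    founders = [i for i in order if ped.members[i].is_founder]

    for attempt in range(1, max_resamples + 1):
        alleles: Dict[str, int] = {}
        for f in founders:
            if introducer is not None:
                alleles[f] = 1 if f == introducer else 0
            else:
                if rng.random() < carrier_frequency:
                    alleles[f] = 2 if (hom_rate and rng.random() < hom_rate) else 1
                else:
                    alleles[f] = 0
        for i in order:
            m = ped.members[i]
            if m.is_founder:
                continue
            inherited = 0
            for parent in (m.father, m.mother):
                if rng.random() < alleles[parent] / 2:
                    inherited += 1
            alleles[i] = inherited
        affection = {}
        for i in order:
            p = penetrance if alleles[i] > 0 else phenocopy
            affection[i] = AFFECTED if rng.random() < p else UNAFFECTED
        if require_affected is None:
            return GeneDropResult(alleles, affection, attempt - 1)
        slots = list(probands or [])
        n_aff = sum(1 for s in slots if affection[s] == AFFECTED)
        if n_aff >= require_affected:
            if attempt > 1:
                logger.debug(
                    "family %s: ascertainment met after %d resamples",
                    ped.family_id, attempt - 1,
                )
            return GeneDropResult(alleles, affection, attempt - 1)
    raise RuntimeError(
        f"family {ped.family_id}: ascertainment not met in {max_resamples} resamples"
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BackgroundLocus:
    interval: GenomicInterval
    cnv_type: str
    frequency: float            # carrier frequency
    jitter_bp: int = 300
    in_dgv: bool = True


@dataclass(frozen=True)
class PlantedCNV:
    interval: GenomicInterval
    cnv_type: str


def default_background_loci() -> List[BackgroundLocus]:
    """A fixed pool of synthetic CNV polymorphisms spanning the carrier-
    frequency range from rare to common."""
    freqs = [0.002, 0.005, 0.008, 0.012, 0.02, 0.03, 0.05, 0.08, 0.12, 0.2]
    loci = []
    for k, f in enumerate(freqs):
        chrom = str(2 * k + 1)
        start = 10_000_000 + 3_000_000 * k
        size = 20_000 + 15_000 * k
        cnv_type = "del" if k % 2 == 0 else "dup"
        loci.append(
            BackgroundLocus(
                GenomicInterval(chrom, start, start + size), cnv_type, f,
                jitter_bp=300, in_dgv=f >= 0.008,
            )
        )
    return loci


def default_planted_loci(n: int = 12) -> List[PlantedCNV]:
    """Synthetic dominant risk CNVs, one candidate locus per target
    family, placed away from the background pool."""
    out = []
    for k in range(n):
        chrom = str((k % 22) + 1)
        start = 80_000_000 + 1_000_000 * k
        size = 15_000 + 25_000 * k
        out.append(
            PlantedCNV(GenomicInterval(chrom, start, start + size),
                       "del" if k % 3 == 0 else "dup")
        )
    return out


@dataclass
class SimulationConfig:
    """Study-design parameters for cohort simulation.

    The defaults are the generator's statement of the study conditions:
    42 families (28/8/6 with 2/3/4 affected cousins), a dominant risk CNV
    with penetrance 0.6 and phenocopy rate 0.001, and a 727 + 111 control
    cohort split over two recruiting centers.
    """

    family_structure_counts: Dict[int, int] = field(
        default_factory=lambda: {2: 28, 3: 8, 4: 6}
    )
    penetrance: float = 0.6
    phenocopy: float = 0.001
    background_loci: List[BackgroundLocus] = field(default_factory=default_background_loci)
    planted: List[PlantedCNV] = field(default_factory=default_planted_loci)
    control_cohorts: Dict[str, Dict[str, int]] = field(
        default_factory=lambda: {
            "EUR": {"HIHG": 465, "NBC": 262},
            "AA": {"HIHG": 100, "NBC": 11},
        }
    )
    n_african_american_families: int = 1
    planted_jitter_bp: int = 300
    dgv_reference_size: int = 9200
    dgv_record_cap: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.penetrance, self.phenocopy):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for locus in self.background_loci:
            if not 0 <= locus.frequency <= 1:
                raise ValueError(f"background frequency outside [0, 1]: {locus}")

    @property
    def cohort_size_by_ancestry(self) -> Dict[str, int]:
        return {anc: sum(c.values()) for anc, c in self.control_cohorts.items()}


@dataclass
class TruthRecord:
    locus_id: str
    interval: GenomicInterval
    cnv_type: str
    family_id: str
    planted: bool
    introducer: str
    carriers: List[str]
    typed_carriers: List[str]
    transmission: str
    expected_retained: bool


@dataclass
class Cohort:
    peds: Dict[str, Pedigree]
    probands: Dict[str, List[str]]
    calls: List[CNVCall]
    qc_metrics: Dict[str, SampleQCMetrics]
    control_table: PopulationCNVTable
    dgv_table: PopulationCNVTable
    truth_log: List[TruthRecord]
    ancestry_by_family: Dict[str, str]
    config: SimulationConfig


def _jitter(iv: GenomicInterval, jitter_bp: int, rng: np.random.Generator) -> GenomicInterval:
    """Perturb both boundaries uniformly within +-jitter, capped so that
    reciprocal overlap with the locus definition stays >= 50%."""
    j = min(jitter_bp, interval_length(iv) // 5)
    if j == 0:
        return iv
    ds = int(rng.integers(-j, j + 1))
    de = int(rng.integers(-j, j + 1))
    return GenomicInterval(iv.chrom, iv.start + ds, iv.end + de)


def _num_snps(iv: GenomicInterval, rng: np.random.Generator) -> int:
    base = max(3, interval_length(iv) // 2000)
    return int(base + rng.integers(0, 3))


def simulate_cohort(config: Optional[SimulationConfig] = None, seed: Optional[int] = None) -> Cohort:
    """Generate the full in-memory cohort, deterministically per seed."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    # families: planted loci are assigned round-robin to the first families
    structures: List[int] = []
    for count in sorted(config.family_structure_counts):
        structures += [count] * config.family_structure_counts[count]
    peds: Dict[str, Pedigree] = {}
    probands: Dict[str, List[str]] = {}
    ancestry: Dict[str, str] = {}
    fam_ids: List[str] = []
    for k, count in enumerate(structures):
        fam = f"SIM{k:03d}"
        sex_mode = "female" if k % 2 == 0 else "mixed"
        ped, slots = generate_pedigree(count, fam, transmitting_sex=sex_mode)
        peds[fam] = ped
        probands[fam] = slots
        ancestry[fam] = "AA" if k < config.n_african_american_families else "EUR"
        fam_ids.append(fam)

    planted_family: Dict[str, List[PlantedCNV]] = {f: [] for f in fam_ids}
    for k, planted in enumerate(config.planted):
        planted_family[fam_ids[k % len(fam_ids)]].append(planted)

    calls: List[CNVCall] = []
    truth: List[TruthRecord] = []
    affection_final: Dict[str, Dict[str, str]] = {}

    for fam in fam_ids:
        ped = peds[fam]
        slots = probands[fam]
        required = len(slots)
        fam_planted = planted_family[fam]
        if fam_planted:
            drop = gene_drop(
                ped, rng,
                introducer=f"{fam}_f1",
                penetrance=config.penetrance,
                phenocopy=config.phenocopy,
                probands=slots,
                require_affected=required,
            )
            affection = drop.affection
        else:
            # families without a planted risk variant are ascertained as
            # such: probands affected, everyone else unaffected
            drop = None
            affection = {
                i: (AFFECTED if i in slots else UNAFFECTED) for i in ped.members
            }
        for i, m in ped.members.items():
            m.affection = affection[i] if m.dna_available or i in affection else m.affection
            if m.is_founder:
                m.affection = UNKNOWN
        affection_final[fam] = affection

        typed = set(ped.genotyped_ids())
        for idx, planted in enumerate(fam_planted):
            locus_id = f"planted_{planted.interval.chrom}_{planted.interval.start}"
            carriers = sorted(drop.carriers)
            typed_carriers = sorted(drop.carriers & typed)
            for sid in typed_carriers:
                iv = _jitter(planted.interval, config.planted_jitter_bp, rng)
                cn = (0 if drop.alleles[sid] >= 2 else 1) if planted.cnv_type == "del" \
                    else (4 if drop.alleles[sid] >= 2 else 3)
                calls.append(CNVCall(sid, iv, cn, _num_snps(iv, rng), source="sim"))
            truth.append(
                TruthRecord(
                    locus_id, planted.interval, planted.cnv_type, fam, True,
                    f"{fam}_f1", carriers, typed_carriers,
                    ped.infer_transmission(set(typed_carriers)).label
                    if typed_carriers else "undetermined",
                    expected_retained=False,  # finalized below
                )
            )

        for locus in config.background_loci:
            bdrop = gene_drop(
                ped, rng, carrier_frequency=locus.frequency,
                penetrance=0.0, phenocopy=0.0,
            )
            if not bdrop.carriers:
                continue
            locus_id = f"bg_{locus.interval.chrom}_{locus.interval.start}"
            typed_carriers = sorted(bdrop.carriers & typed)
            for sid in typed_carriers:
                iv = _jitter(locus.interval, locus.jitter_bp, rng)
                cn = (0 if bdrop.alleles[sid] >= 2 else 1) if locus.cnv_type == "del" \
                    else (4 if bdrop.alleles[sid] >= 2 else 3)
                calls.append(CNVCall(sid, iv, cn, _num_snps(iv, rng), source="sim"))
            truth.append(
                TruthRecord(
                    locus_id, locus.interval, locus.cnv_type, fam, False,
                    "", sorted(bdrop.carriers), typed_carriers, "", False,
                )
            )

    # control cohort
    control_records: List[PopulationRecord] = []
    for anc in sorted(config.control_cohorts):
        for cohort in sorted(config.control_cohorts[anc]):
            n = config.control_cohorts[anc][cohort]
            for i in range(n):
                sid = f"CTRL_{anc}_{cohort}_{i:04d}"
                for locus in config.background_loci:
                    if rng.random() < locus.frequency:
                        iv = _jitter(locus.interval, locus.jitter_bp, rng)
                        control_records.append(
                            PopulationRecord(iv, locus.cnv_type, cohort, anc, sid)
                        )
    control_table = PopulationCNVTable(control_records, config.cohort_size_by_ancestry)

    dgv_records: List[PopulationRecord] = []
    for locus in config.background_loci:
        if not locus.in_dgv:
            continue
        n = min(config.dgv_record_cap,
                int(round(locus.frequency * config.dgv_reference_size)))
        for i in range(n):
            dgv_records.append(
                PopulationRecord(
                    locus.interval, locus.cnv_type, "DGV", "NA",
                    f"DGV_{locus.interval.chrom}_{locus.interval.start}_{i:04d}",
                )
            )
    dgv_table = PopulationCNVTable(dgv_records)

    # QC metrics: all samples well within the passing region
    n_calls: Dict[str, int] = {}
    for c in calls:
        n_calls[c.sample_id] = n_calls.get(c.sample_id, 0) + 1
    qc_metrics: Dict[str, SampleQCMetrics] = {}
    for fam in fam_ids:
        for sid in peds[fam].genotyped_ids():
            qc_metrics[sid] = SampleQCMetrics(
                sample_id=sid,
                sdlrr=float(np.round(rng.uniform(0.10, 0.28), 4)),
                n_cnvs=n_calls.get(sid, 0),
                call_rate=float(np.round(rng.uniform(0.96, 0.999), 4)),
            )

    cohort = Cohort(
        peds=peds, probands=probands, calls=calls, qc_metrics=qc_metrics,
        control_table=control_table, dgv_table=dgv_table, truth_log=truth,
        ancestry_by_family=ancestry, config=config,
    )
    _finalize_expected_retained(cohort)
    return cohort


def _finalize_expected_retained(cohort: Cohort) -> None:
    """Planting-log oracle: a truth locus is expected to survive the
    screen iff every genotyped affected member of its family carries it,
    at most one married-in member carries it, a single-origin descent
    explanation exists, and the realized ancestry-matched control carrier
    frequency is below the threshold."""
    threshold = Fraction(15, 1000)
    for rec in cohort.truth_log:
        ped = cohort.peds[rec.family_id]
        affected_dna = set(ped.affected_with_dna())
        if len(affected_dna) < 2 or not affected_dna <= set(rec.typed_carriers):
            rec.expected_retained = False
            continue
        parts = ped.classify_members()
        married_in_carriers = set(rec.typed_carriers) & set(parts["married_in"])
        if len(married_in_carriers) > 1:
            rec.expected_retained = False
            continue
        if not ped.infer_transmission(set(rec.typed_carriers)).consistent:
            rec.expected_retained = False
            continue
        anc = cohort.ancestry_by_family[rec.family_id]
        freq = cohort.control_table.carrier_frequency(rec.interval, rec.cnv_type, anc)
        rec.expected_retained = freq < threshold


def emit_cohort(
    config: Optional[SimulationConfig] = None,
    out_dir=None,
    seed: Optional[int] = None,
) -> Cohort:
    """Simulate a cohort and, if ``out_dir`` is given, write every
    pipeline input file plus the truth log (deterministic per seed)."""
    cohort = simulate_cohort(config, seed)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for fam, ped in cohort.peds.items():
            ped.ancestry = cohort.ancestry_by_family[fam]  # type: ignore[attr-defined]
        write_ped(cohort.peds, out / "families.ped")
        write_penncnv_calls(sorted(cohort.calls, key=lambda c: (
            c.sample_id, c.interval.chrom, c.interval.start)), out / "calls.rawcnv")
        write_qc_metrics(cohort.qc_metrics, out / "qc_metrics.tsv")
        write_population_table(cohort.control_table, out / "controls.tsv")
        write_population_table(cohort.dgv_table, out / "dgv.tsv")
        with open(out / "truth_log.tsv", "w") as fh:
            fh.write(
                "locus_id\tchrom\tstart\tend\ttype\tfamily\tplanted\tintroducer\t"
                "carriers\ttyped_carriers\ttransmission\texpected_retained\n"
            )
            for r in cohort.truth_log:
                fh.write(
                    f"{r.locus_id}\t{r.interval.chrom}\t{r.interval.start}\t"
                    f"{r.interval.end}\t{r.cnv_type}\t{r.family_id}\t"
                    f"{int(r.planted)}\t{r.introducer}\t{','.join(r.carriers)}\t"
                    f"{','.join(r.typed_carriers)}\t{r.transmission}\t"
                    f"{int(r.expected_retained)}\n"
                )
    return cohort


def pipeline_config_for(cohort: Cohort, **overrides) -> RunConfig:
    """A RunConfig matched to a simulated cohort's ancestry map and
    control cohort sizes."""
    cfg = RunConfig(
        ancestry_by_family=dict(cohort.ancestry_by_family),
        cohort_size_by_ancestry=dict(cohort.config.cohort_size_by_ancestry),
        **overrides,
    )
    return cfg
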