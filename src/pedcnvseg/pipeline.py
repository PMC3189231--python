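"""The multi-step co-segregation filter over extended families.

Stages, in order:

1. QC — sample gates (SDLRR, CNV count, call rate) and call gates
   (probe minimum, autosomes only).
2. Shared-CNV screen — per family, find loci where *every* genotyped
   affected member carries the same CNV (type-matched, reciprocal
   overlap); the candidate interval is the intersection across the
   affected carriers' calls.
3. Segregation filter — reject candidates carried by more than one
   married-in unaffected individual, or whose carriers cannot be
   explained by descent from a single introducing ancestor through
   carrier-or-untyped paths.  Unaffected blood-relative carriers are
   permitted: the model is dominant with incomplete penetrance.
4. Population-frequency filter — reject candidates whose
   ancestry-matched control carrier frequency reaches the threshold
   (default 1.5%); a DGV-style catalogue count is annotated but never
   grounds rejection.
5. Prioritization — tier 1: absent from controls and the catalogue and
   overlapping a literature region; tier 2: absent from both, novel;
   tier 3: low-frequency in controls or present in the catalogue.
6. Gene annotation — whole-gene / exonic-portion / intronic context, or
   nearest gene with signed distance.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .core import (
    CNVCall,
    CandidateCNV,
    GeneContext,
    GenomicInterval,
    interval_length,
    intersect_all,
    is_same_cnv,
    overlap_bp,
    same_locus,
)
from .io import (
    GeneModel,
    LiteratureRegion,
    PopulationCNVTable,
    RunConfig,
    read_genes_bed,
    read_literature_bed,
    read_ped,
    read_penncnv_calls,
    read_population_table,
    read_qc_metrics,
    write_candidate_report,
)
from .pedigree import AFFECTED, Pedigree
from .qc import apply_sample_qc, call_qc

logger = logging.getLogger(__name__)


@dataclass
class FilterTrace:
    """Per-stage bookkeeping: candidate verdicts and family-level counts."""

    events: List[Tuple[str, str, str, str]] = field(default_factory=list)
    stage_counts: Dict[str, Dict[str, int]] = field(default_factory=dict)

    def record(self, stage: str, candidate_key: str, verdict: str, reason: str = "") -> None:
        self.events.append((stage, candidate_key, verdict, reason))
        counts = self.stage_counts.setdefault(stage, {"entering": 0, "retained": 0, "rejected": 0})
        counts["entering"] += 1
        if verdict == "retained":
            counts["retained"] += 1
        else:
            counts["rejected"] += 1

    def conserved(self) -> bool:
        return all(
            c["entering"] == c["retained"] + c["rejected"]
            for c in self.stage_counts.values()
        )


def _candidate_key(c: CandidateCNV) -> str:
    return f"{c.family_id}:{c.cnv_type}:{c.interval}"


# ---------------------------------------------------------------------------
# stage 2: family-wise shared-CNV screen
# ---------------------------------------------------------------------------


def family_shared_candidates(
    ped: Pedigree,
    calls: Sequence[CNVCall],
    config: RunConfig,
    qc_passed: Optional[Set[str]] = None,
) -> List[CandidateCNV]:
    """Loci at which every genotyped, QC-passed affected member carries
    the same CNV.

    Groups are maximal cliques under the same-CNV predicate among the
    affected members' calls; a clique must contribute one call per
    affected member.  When several maximal groups cover the same affected
    set, the longest intersection wins (others are logged).  Carriers of
    any affection status matching the candidate are recorded afterwards.
    """
    frac, mode = config.overlap_fraction, config.overlap_mode
    affected = [
        i for i in ped.affected_with_dna() if qc_passed is None or i in qc_passed
    ]
    if len(affected) < 2:
        logger.warning(
            "family %s skipped: fewer than two genotyped affected members",
            ped.family_id,
        )
        return []
    affected_set = set(affected)
    member_calls = [c for c in calls if c.sample_id in ped.members]
    by_key: Dict[Tuple[str, str], List[CNVCall]] = defaultdict(list)
    for c in member_calls:
        by_key[(c.interval.chrom, c.cnv_type)].append(c)

    candidates: List[CandidateCNV] = []
    for (chrom, cnv_type), group in sorted(by_key.items()):
        aff_calls = [c for c in group if c.sample_id in affected_set]
        if {c.sample_id for c in aff_calls} != affected_set:
            continue
        graph = nx.Graph()
        graph.add_nodes_from(range(len(aff_calls)))
        for i in range(len(aff_calls)):
            for j in range(i + 1, len(aff_calls)):
                if is_same_cnv(aff_calls[i], aff_calls[j], frac, mode):
                    graph.add_edge(i, j)
        best_by_interval: Dict[GenomicInterval, None] = {}
        complete: List[GenomicInterval] = []
        for clique in nx.find_cliques(graph):
            samples = defaultdict(list)
            for idx in clique:
                samples[aff_calls[idx].sample_id].append(aff_calls[idx])
            if set(samples) != affected_set:
                continue
            # one call per member: keep the longest when a sample has several
            chosen = [
                max(cs, key=lambda c: interval_length(c.interval))
                for cs in samples.values()
            ]
            iv = intersect_all([c.interval for c in chosen])
            if iv is not None:
                complete.append(iv)
        if not complete:
            continue
        complete.sort(key=lambda iv: (-interval_length(iv), iv.start))
        winner = complete[0]
        for other in complete[1:]:
            if other != winner:
                logger.info(
                    "family %s %s chr%s: alternative shared interval %s superseded by %s",
                    ped.family_id, cnv_type, chrom, other, winner,
                )
        cand = CandidateCNV(family_id=ped.family_id, interval=winner, cnv_type=cnv_type)
        carriers: Set[str] = set()
        for c in member_calls:
            if c.cnv_type == cnv_type and same_locus(
                winner, cnv_type, c.interval, c.cnv_type, frac, mode
            ):
                carriers.add(c.sample_id)
        parts = ped.classify_members()
        cand.affected_carriers = sorted(carriers & set(parts[AFFECTED]))
        cand.unaffected_blood_carriers = sorted(carriers & set(parts["unaffected_blood"]))
        cand.married_in_carriers = sorted(carriers & set(parts["married_in"]))
        candidates.append(cand)
    # de-duplicate identical loci emitted from overlapping call groups
    uniq: Dict[str, CandidateCNV] = {}
    for cand in candidates:
        uniq.setdefault(_candidate_key(cand), cand)
    return list(uniq.values())


# ---------------------------------------------------------------------------
# stage 3: married-in / segregation filter
# ---------------------------------------------------------------------------


def segregation_filter(candidate: CandidateCNV, ped: Pedigree, config: Optional[RunConfig] = None) -> CandidateCNV:
    """Reject candidates carried by >1 married-in unaffected individual or
    without a single-origin descent explanation."""
    config = config or RunConfig()
    if len(candidate.married_in_carriers) > 1:
        candidate.verdict = "rejected"
        candidate.reason = "married_in>1"
        return candidate
    result = ped.infer_transmission(set(candidate.carriers))
    candidate.transmission = result.label
    candidate.diagnostics["introducers"] = sorted(result.introducers)
    candidate.diagnostics["feasible_origins"] = result.diagnostics.get("feasible_origins", [])
    if config.require_single_origin and not result.consistent:
        candidate.verdict = "rejected"
        candidate.reason = "no_segregation"
        return candidate
    candidate.verdict = "retained"
    candidate.reason = ""
    return candidate


# ---------------------------------------------------------------------------
# stage 4: population-frequency filter
# ---------------------------------------------------------------------------


def population_filter(
    candidate: CandidateCNV,
    control_table: PopulationCNVTable,
    dgv_table: Optional[PopulationCNVTable],
    family_ancestry: str,
    config: RunConfig,
) -> CandidateCNV:
    """Annotate control frequencies per ancestry and reject at the
    ancestry-matched threshold; the DGV-style count never rejects."""
    frac, mode = config.overlap_fraction, config.overlap_mode
    if family_ancestry not in control_table.cohort_size_by_ancestry:
        raise KeyError(
            f"family ancestry {family_ancestry!r} absent from control cohort sizes"
        )
    counts = candidate.control_carrier_counts = {
        anc: dict(c)
        for anc, c in control_table.carrier_counts(
            candidate.interval, candidate.cnv_type, frac, mode
        ).items()
    }
    freqs: Dict[str, Fraction] = {}
    for anc, size in control_table.cohort_size_by_ancestry.items():
        n = sum(counts.get(anc, {}).values())
        freqs[anc] = Fraction(n, size)
    candidate.control_frequency_by_ancestry = freqs
    if dgv_table is not None:
        candidate.dgv_count = dgv_table.total_carriers(
            candidate.interval, candidate.cnv_type, frac, mode
        )
    matched = freqs[family_ancestry]
    if matched >= Fraction(config.frequency_threshold).limit_denominator(10**9):
        candidate.verdict = "rejected"
        candidate.reason = "control_frequency"
    return candidate


# ---------------------------------------------------------------------------
# stage 5: prioritization
# ---------------------------------------------------------------------------


def literature_overlap_class(
    candidate: CandidateCNV,
    regions: Sequence[LiteratureRegion],
    config: RunConfig,
) -> str:
    """similar-breakpoints (reciprocal overlap with a reported CNV region)
    beats partial-of-larger-region (candidate inside a reported region)."""
    best = "none"
    for region in regions:
        iv = region.interval
        if iv.chrom != candidate.interval.chrom:
            continue
        try:
            similar = same_locus(
                candidate.interval, candidate.cnv_type, iv, candidate.cnv_type,
                config.overlap_fraction, "reciprocal",
            )
        except ValueError:
            continue
        if similar:
            return "similar-breakpoints"
        contained = (
            iv.start <= candidate.interval.start and candidate.interval.end <= iv.end
        )
        if contained:
            best = "partial-of-larger-region"
    return best


def prioritize(
    candidate: CandidateCNV,
    literature_regions: Sequence[LiteratureRegion],
    config: Optional[RunConfig] = None,
) -> CandidateCNV:
    config = config or RunConfig()
    candidate.literature_overlap = literature_overlap_class(
        candidate, literature_regions, config
    )
    total_controls = sum(
        sum(c.values()) for c in candidate.control_carrier_counts.values()
    )
    absent = total_controls == 0 and candidate.dgv_count == 0
    if absent and candidate.literature_overlap != "none":
        candidate.priority_tier = 1
    elif absent:
        candidate.priority_tier = 2
    else:
        candidate.priority_tier = 3
    return candidate


# ---------------------------------------------------------------------------
# stage 6: gene context
# ---------------------------------------------------------------------------


def annotate_genes(
    candidate: CandidateCNV, gene_models: Sequence[GeneModel]
) -> CandidateCNV:
    """Classify overlapped genes, or report the nearest gene and its
    signed, strand-aware distance when none overlaps."""
    iv = candidate.interval
    hits: List[GeneContext] = []
    for gene in gene_models:
        g = gene.interval
        if g.chrom != iv.chrom or overlap_bp(iv, g) == 0:
            continue
        if iv.start <= g.start and g.end <= iv.end:
            relation = "whole-gene"
        elif any(overlap_bp(iv, e) > 0 for e in gene.exons):
            relation = "exonic-portion"
        elif g.start <= iv.start and iv.end <= g.end:
            relation = "intronic"
        else:
            relation = "partial"
        hits.append(GeneContext(gene=gene.name, relation=relation))
    if hits:
        candidate.genes = sorted(hits, key=lambda h: h.gene)
        return candidate
    # nearest gene on the chromosome
    nearest: Optional[Tuple[int, GeneModel]] = None
    for gene in gene_models:
        g = gene.interval
        if g.chrom != iv.chrom:
            continue
        dist = g.start - iv.end if g.start > iv.end else iv.start - g.end
        if nearest is None or dist < nearest[0]:
            nearest = (dist, gene)
    if nearest is None:
        candidate.genes = []
        return candidate
    dist, gene = nearest
    g = gene.interval
    before_gene = iv.end < g.start
    if gene.strand == "-":
        direction = "upstream" if not before_gene else "downstream"
    else:
        direction = "upstream" if before_gene else "downstream"
    candidate.genes = [
        GeneContext(gene=gene.name, relation="nearest", distance_bp=dist, direction=direction)
    ]
    return candidate


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    candidates: List[CandidateCNV]
    trace: FilterTrace
    qc_verdicts: Dict[str, Tuple[str, List[str]]] = field(default_factory=dict)
    call_exclusions: Dict[str, int] = field(default_factory=dict)

    @property
    def retained(self) -> List[CandidateCNV]:
        return [c for c in self.candidates if c.verdict == "retained"]


def run_pipeline(
    peds: Dict[str, Pedigree],
    calls: Sequence[CNVCall],
    qc_metrics: Optional[Dict[str, object]],
    control_table: PopulationCNVTable,
    dgv_table: Optional[PopulationCNVTable],
    config: RunConfig,
    literature_regions: Sequence[LiteratureRegion] = (),
    gene_models: Sequence[GeneModel] = (),
) -> PipelineResult:
    """End-to-end deterministic run over in-memory inputs."""
    trace = FilterTrace()

    if qc_metrics:
        qc_passed_list, qc_verdicts = apply_sample_qc(qc_metrics, config)
        qc_passed: Optional[Set[str]] = set(qc_passed_list)
        calls = [c for c in calls if c.sample_id in qc_passed]
    else:
        qc_passed, qc_verdicts = None, {}
    calls, call_excl = call_qc(calls, config)

    all_candidates: List[CandidateCNV] = []
    for fam in sorted(peds):
        ped = peds[fam]
        fam_cands = family_shared_candidates(ped, calls, config, qc_passed)
        for cand in fam_cands:
            trace.record("shared_screen", _candidate_key(cand), "retained")
        all_candidates.extend(fam_cands)

    survivors: List[CandidateCNV] = []
    for cand in all_candidates:
        cand = segregation_filter(cand, peds[cand.family_id], config)
        trace.record("segregation", _candidate_key(cand), cand.verdict, cand.reason)
        if cand.verdict == "retained":
            survivors.append(cand)

    stage4: List[CandidateCNV] = []
    for cand in survivors:
        cand = population_filter(
            cand, control_table, dgv_table, config.family_ancestry(cand.family_id), config
        )
        trace.record("population", _candidate_key(cand), cand.verdict, cand.reason)
        if cand.verdict == "retained":
            stage4.append(cand)

    for cand in stage4:
        prioritize(cand, literature_regions, config)
        annotate_genes(cand, gene_models)

    return PipelineResult(
        candidates=all_candidates,
        trace=trace,
        qc_verdicts=qc_verdicts,
        call_exclusions=dict(call_excl),
    )


def run_pipeline_files(
    calls_path,
    ped_path,
    controls_path,
    dgv_path=None,
    literature_path=None,
    genes_path=None,
    qc_path=None,
    config: Optional[RunConfig] = None,
    out_dir=None,
) -> PipelineResult:
    """File-based wrapper around :func:`run_pipeline`; writes the TSV and
    JSON reports when ``out_dir`` is given."""
    config = config or RunConfig()
    peds = read_ped(ped_path)
    for fam, ped in peds.items():
        anc = getattr(ped, "ancestry", None)
        if anc and fam not in config.ancestry_by_family:
            config.ancestry_by_family[fam] = anc
    calls = read_penncnv_calls(calls_path)
    control_table = read_population_table(controls_path, config.cohort_size_by_ancestry)
    dgv_table = read_population_table(dgv_path) if dgv_path else None
    literature = read_literature_bed(literature_path) if literature_path else []
    genes = read_genes_bed(genes_path) if genes_path else []
    qc_metrics = read_qc_metrics(qc_path) if qc_path else None

    result = run_pipeline(
        peds, calls, qc_metrics, control_table, dgv_table, config, literature, genes
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ancestries = sorted(control_table.cohort_size_by_ancestry)
        write_candidate_report(result.retained, out_dir / "candidates.tsv", "tsv", ancestries)
        write_candidate_report(result.retained, out_dir / "candidates.json", "json", ancestries)
    return result
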