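"""Sample- and call-level quality control gates.

Sample gates mirror the array-QC practice for intensity-based CNV calling:
a sample fails with SDLRR (standard deviation of the normalized Log R
ratio) >= 0.4, more than 300 detected CNVs, or a genotyping call rate
below 95%.  Samples in the noisy-but-usable zone (0.3 < SDLRR < 0.4 and
100-300 CNVs) are flagged for review; by default they are retained with a
logged flag, since the original manual mosaicism review cannot be
automated, and a strict mode excludes them instead.

Call gates: a CNV call needs at least three supporting probes, and the
analysis is restricted to autosomes (hemizygosity in males and X
inactivation in females make sex-chromosome dosage calls incomparable).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from .core import CNVCall
from .io import RunConfig

logger = logging.getLogger(__name__)

PASS = "pass"
REVIEW = "review"
FAIL = "fail"


@dataclass
class SampleQCMetrics:
    sample_id: str
    sdlrr: float
    n_cnvs: int
    call_rate: float

    def __post_init__(self) -> None:
        for name in ("sdlrr", "n_cnvs", "call_rate"):
            if getattr(self, name) is None:
                raise ValueError(f"sample {self.sample_id}: missing QC metric {name}")
        if self.sdlrr < 0 or self.n_cnvs < 0 or not 0 <= self.call_rate <= 1:
            raise ValueError(f"sample {self.sample_id}: QC metric out of range")


def sample_qc(metrics: SampleQCMetrics, config: RunConfig) -> Tuple[str, List[str]]:
    """Classify a sample as pass / review / fail with reason codes."""
    qc = config.qc
    reasons: List[str] = []
    if metrics.sdlrr >= qc.sdlrr_max:
        reasons.append("SDLRR")
    if metrics.n_cnvs > qc.max_cnvs:
        reasons.append("max_cnvs")
    if metrics.call_rate < qc.min_call_rate:
        reasons.append("call_rate")
    if reasons:
        return FAIL, reasons
    lo, hi = qc.review_sdlrr
    clo, chi = qc.review_cnvs
    if lo < metrics.sdlrr < hi and clo <= metrics.n_cnvs <= chi:
        return REVIEW, ["review_zone"]
    return PASS, []


def apply_sample_qc(
    metrics: Dict[str, SampleQCMetrics], config: RunConfig
) -> Tuple[List[str], Dict[str, Tuple[str, List[str]]]]:
    """Return ids of samples retained for analysis plus the full verdict map.

    Review samples are retained unless ``config.strict_qc``."""
    verdicts = {sid: sample_qc(m, config) for sid, m in metrics.items()}
    retained = []
    for sid in sorted(verdicts):
        verdict, reasons = verdicts[sid]
        if verdict == FAIL:
            logger.info("sample %s failed QC: %s", sid, ",".join(reasons))
            continue
        if verdict == REVIEW:
            logger.warning("sample %s flagged for review (noisy intensity zone)", sid)
            if config.strict_qc:
                continue
        retained.append(sid)
    return retained, verdicts


def call_qc(
    calls: Sequence[CNVCall], config: RunConfig
) -> Tuple[List[CNVCall], Counter]:
    """Drop calls below the probe minimum or outside the autosomes."""
    retained: List[CNVCall] = []
    excluded: Counter = Counter()
    for call in calls:
        if call.num_snps < config.qc.min_snps:
            excluded["min_snps"] += 1
        elif not call.interval.is_autosomal:
            excluded["autosome"] += 1
        else:
            retained.append(call)
    return retained, excluded
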