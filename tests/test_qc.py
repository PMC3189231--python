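"""Sample- and call-level QC gates."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from pedcnvseg.core import CNVCall, GenomicInterval
from pedcnvseg.io import RunConfig
from pedcnvseg.qc import FAIL, PASS, REVIEW, SampleQCMetrics, call_qc, sample_qc

CFG = RunConfig()


def metrics(sdlrr=0.2, n_cnvs=50, call_rate=0.99):
    return SampleQCMetrics("s", sdlrr, n_cnvs, call_rate)


class TestSampleQC:
    @pytest.mark.parametrize(
        "kwargs,verdict,reason",
        [
            (dict(), PASS, None),
            (dict(sdlrr=0.45), FAIL, "SDLRR"),
            (dict(sdlrr=0.4), FAIL, "SDLRR"),            # < 0.4 is the inclusion rule
            (dict(n_cnvs=301), FAIL, "max_cnvs"),
            (dict(call_rate=0.94), FAIL, "call_rate"),
            (dict(sdlrr=0.35, n_cnvs=150), REVIEW, "review_zone"),
            (dict(sdlrr=0.3, n_cnvs=150), PASS, None),   # boundary outside review zone
            (dict(sdlrr=0.35, n_cnvs=100), REVIEW, "review_zone"),
            (dict(sdlrr=0.35, n_cnvs=99), PASS, None),
            (dict(n_cnvs=300), PASS, None),              # 300 CNVs still included
        ],
    )
    def test_verdicts(self, kwargs, verdict, reason):
        v, reasons = sample_qc(metrics(**kwargs), CFG)
        assert v == verdict
        if reason:
            assert reason in reasons

    def test_missing_metric_never_passes_silently(self):
        with pytest.raises(ValueError):
            SampleQCMetrics("s", None, 50, 0.99)


def mkcall(chrom="22", num_snps=3, cn=1):
    return CNVCall("s", GenomicInterval(chrom, 1000, 2000), cn, num_snps)


class TestCallQC:
    def test_probe_minimum_boundary_inclusive(self):
        retained, excl = call_qc([mkcall(num_snps=3), mkcall(num_snps=2)], CFG)
        assert len(retained) == 1
        assert excl["min_snps"] == 1

    @pytest.mark.parametrize("chrom", ["X", "Y", "MT"])
    def test_non_autosomes_dropped(self, chrom):
        retained, excl = call_qc([mkcall(chrom=chrom)], CFG)
        assert retained == [] and excl["autosome"] == 1

    @settings(derandomize=True, max_examples=100)
    @given(
        snps=st.lists(st.integers(1, 10), min_size=0, max_size=30),
        min_snps=st.integers(1, 8),
    )
    def test_conservation_and_monotonicity(self, snps, min_snps):
        calls = [mkcall(num_snps=k) for k in snps]
        cfg = RunConfig()
        cfg.qc = dataclasses.replace(cfg.qc, min_snps=min_snps)
        retained, excl = call_qc(calls, cfg)
        assert len(retained) + sum(excl.values()) == len(calls)
        # relaxing the probe threshold never shrinks the retained set
        relaxed = RunConfig()
        relaxed.qc = dataclasses.replace(relaxed.qc, min_snps=max(1, min_snps - 2))
        retained_relaxed, _ = call_qc(calls, relaxed)
        assert len(retained_relaxed) >= len(retained)
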