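"""The synthetic-cohort generator: Mendelian soundness, calibration,
determinism, and end-to-end agreement with its own truth log."""

from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from pedcnvseg.core import CNVCall, same_locus
from pedcnvseg.pipeline import run_pipeline
from pedcnvseg.simulate import (
    gene_drop,
    generate_pedigree,
    pipeline_config_for,
    simulate_cohort,
)
from pedcnvseg.pedigree import AFFECTED


class TestTemplates:
    @pytest.mark.parametrize("template,expected_sharing", [
        ("avuncular_pair", Fraction(1, 4)),
        ("first_cousin_pair", Fraction(1, 8)),
        ("second_cousin_pair", Fraction(1, 32)),
    ])
    def test_proband_relatedness(self, template, expected_sharing):
        ped, (a, b) = generate_pedigree(template, "F")
        assert ped.expected_sharing(a, b) == expected_sharing

    @pytest.mark.parametrize("template", [
        "avuncular_pair", "first_cousin_pair", "second_cousin_pair",
        "three_affected", "four_affected",
    ])
    def test_every_template_validates_as_extended_family(self, template):
        ped, probands = generate_pedigree(template, "F")
        assert ped.validate_extended_family() == []
        assert set(probands) <= set(ped.affected_with_dna())

    def test_unknown_template_rejected(self):
        with pytest.raises(ValueError):
            generate_pedigree("nuclear", "F")


class TestGeneDrop:
    def test_planted_full_penetrance_affecteds_all_carry(self):
        rng = np.random.default_rng(1)
        ped, probands = generate_pedigree("first_cousin_pair", "F")
        drop = gene_drop(
            ped, rng, introducer="F_f1", penetrance=1.0, phenocopy=0.0,
            probands=probands, require_affected=2,
        )
        affected = {i for i, a in drop.affection.items() if a == AFFECTED}
        assert affected <= drop.carriers
        assert set(probands) <= drop.carriers

    def test_zero_frequency_locus_has_no_carriers(self):
        rng = np.random.default_rng(2)
        ped, _ = generate_pedigree("first_cousin_pair", "F")
        assert gene_drop(ped, rng, carrier_frequency=0.0).carriers == set()

    def test_invalid_frequency_rejected(self):
        ped, _ = generate_pedigree("first_cousin_pair", "F")
        with pytest.raises(ValueError):
            gene_drop(ped, np.random.default_rng(0), carrier_frequency=1.5)

    def test_founder_assignment_within_exact_binomial_interval(self):
        """1000 founders at carrier frequency 0.2: the realized carrier
        count falls in the central 99% binomial interval."""
        rng = np.random.default_rng(42)
        carriers = 0
        for k in range(500):
            ped, _ = generate_pedigree("first_cousin_pair", f"F{k}")
            drop = gene_drop(ped, rng, carrier_frequency=0.2)
            carriers += sum(
                1 for i in ("f1", "f2") if drop.alleles[f"F{k}_{i}"] > 0
            )
        lo, hi = sps.binom.ppf([0.005, 0.995], 1000, 0.2)
        assert lo <= carriers <= hi


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(seed=123)


class TestCohort:
    def test_family_structure_mix(self, cohort):
        sizes = sorted(len(p) for p in cohort.probands.values())
        assert len(cohort.peds) == 42
        assert sizes.count(2) == 28 and sizes.count(3) == 8 and sizes.count(4) == 6

    def test_mendelian_soundness(self, cohort):
        """Every non-founder carrier has at least one carrier parent."""
        for rec in cohort.truth_log:
            ped = cohort.peds[rec.family_id]
            carriers = set(rec.carriers)
            for iid in rec.carriers:
                m = ped.members[iid]
                if m.is_founder:
                    continue
                assert m.father in carriers or m.mother in carriers

    def test_control_frequency_calibrated(self, cohort):
        """Ascertainment does not bias the controls: the common 20%
        background locus appears at its configured carrier frequency
        (central 99.9% binomial interval, n = 838)."""
        locus = next(l for l in cohort.config.background_loci if l.frequency == 0.2)
        n = sum(cohort.config.cohort_size_by_ancestry.values())
        carriers = sum(
            cohort.control_table.total_carriers(locus.interval, locus.cnv_type, f, m)
            for f, m in [(0.5, "reciprocal")]
        )
        lo, hi = sps.binom.ppf([0.0005, 0.9995], n, 0.2)
        assert lo <= carriers <= hi

    def test_same_seed_reproduces_cohort(self):
        a = simulate_cohort(seed=5)
        b = simulate_cohort(seed=5)
        assert [(c.sample_id, str(c.interval), c.copy_number) for c in a.calls] == [
            (c.sample_id, str(c.interval), c.copy_number) for c in b.calls
        ]
        assert [r.locus_id for r in a.truth_log] == [r.locus_id for r in b.truth_log]

    def test_pipeline_retains_exactly_what_the_truth_log_predicts(self, cohort):
        cfg = pipeline_config_for(cohort)
        res = run_pipeline(
            cohort.peds, cohort.calls, cohort.qc_metrics,
            cohort.control_table, cohort.dgv_table, cfg,
        )
        expected = [r for r in cohort.truth_log if r.expected_retained]

        def match(c, r):
            return c.family_id == r.family_id and same_locus(
                c.interval, c.cnv_type, r.interval, r.cnv_type
            )

        assert all(any(match(c, r) for r in expected) for c in res.retained)
        assert all(any(match(c, r) for c in res.retained) for r in expected)
        assert sum(r.planted for r in expected) >= 10


class TestParameterRecovery:
    def _analytic_retention_given_ascertainment(self, pen, phi):
        """Exhaustive enumeration over carrier configurations of the
        first-cousin template with a heterozygous founder introducer:
        P(all typed affecteds carry | both probands affected)."""
        num = 0.0
        den = 0.0
        for b1 in (0, 1):
            for b2 in (0, 1):
                for p1 in (0, 1) if b1 else (0,):
                    for p2 in (0, 1) if b2 else (0,):
                        w = 0.25  # the two blood sibs
                        w *= (0.5 if b1 else 1.0) * (0.5 if b2 else 1.0)
                        aff1 = pen if p1 else phi
                        aff2 = pen if p2 else phi
                        den += w * aff1 * aff2
                        if p1 and p2:
                            # typed non-carriers: two spouses + non-carrier sibs
                            k = 2 + (b1 == 0) + (b2 == 0)
                            num += w * pen * pen * (1 - phi) ** k
        return num / den

    def test_retention_rate_brackets_analytic_probability(self):
        pen, phi = 0.6, 0.05
        p_analytic = self._analytic_retention_given_ascertainment(pen, phi)
        rng = np.random.default_rng(77)
        from pedcnvseg.io import PopulationCNVTable, RunConfig

        empty_controls = PopulationCNVTable([], {"EUR": 727})
        locus = None
        retained = 0
        n_rep = 50
        for _ in range(n_rep):
            ped, probands = generate_pedigree("first_cousin_pair", "R")
            drop = gene_drop(
                ped, rng, introducer="R_f1", penetrance=pen, phenocopy=phi,
                probands=probands, require_affected=2,
            )
            for iid, m in ped.members.items():
                if not m.is_founder:
                    m.affection = drop.affection[iid]
            from pedcnvseg.core import GenomicInterval

            locus = GenomicInterval("8", 50_000_000, 50_040_000)
            calls = [
                CNVCall(s, locus, 1, 10)
                for s in sorted(drop.carriers & set(ped.genotyped_ids()))
            ]
            res = run_pipeline({"R": ped}, calls, None, empty_controls, None, RunConfig())
            retained += len(res.retained)
        lo, hi = sps.binom.ppf([0.0005, 0.9995], n_rep, p_analytic)
        assert lo <= retained <= hi
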