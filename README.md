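# pedcnv-seg

Co-segregation analysis of copy-number variants (CNVs) in extended
pedigrees.

## The problem

Rare, heritable CNVs are a significant component of autism spectrum
disorder (ASD) risk, but in case–control designs they drown in the
thousands of benign copy-number polymorphisms every genome carries.
Extended multiplex families offer a way out: an avuncular pair shares
25% of the autosomal genome by chance, first cousins 12.5% and second
cousins 3.125% (2φ for kinship coefficient φ), so a CNV present in
*every* affected member of an extended family is a strong candidate for
an inherited risk variant — a dominant allele with incomplete
penetrance passing through unaffected carriers.

`pedcnv-seg` implements that discovery screen as a tested pipeline,
from per-sample array CNV calls and PED pedigrees to prioritized
candidate loci:

1. **QC** — samples fail at SDLRR ≥ 0.4, > 300 detected CNVs or call
   rate < 95% (noisy-zone samples are flagged for review); calls need
   ≥ 3 probes and the analysis is restricted to autosomes.
2. **Shared-CNV screen** — per family, loci where every genotyped
   affected member carries the same CNV. Two records are *the same CNV*
   when types match and they overlap reciprocally by ≥ 50% of both
   lengths; the candidate interval is the intersection across carriers.
3. **Segregation filter** — reject candidates carried by more than one
   married-in spouse, or whose carriers cannot descend from a single
   introducing ancestor through carrier-or-untyped paths. Unaffected
   blood-relative carriers are expected (incomplete penetrance) and the
   parental transmission route (maternal / paternal / both) is labelled.
4. **Population-frequency filter** — reject candidates whose
   ancestry-matched control carrier frequency is ≥ 1.5%; a DGV-style
   catalogue count is annotated but never grounds rejection.
5. **Prioritization and gene context** — tier 1: absent from controls
   and catalogue with literature support; tier 2: absent from both,
   novel; tier 3: rare-in-controls or catalogued. Overlapped genes are
   classified whole-gene / exonic-portion / intronic, otherwise the
   nearest gene and strand-aware distance is reported.

Supporting statistics (two-sided Fisher's exact test by
point-probability summation, tie-corrected Kruskal–Wallis, exact
carrier-frequency arithmetic) and a seeded synthetic-cohort generator
(pedigree templates, Mendelian gene dropping with penetrance and
phenocopy, background polymorphisms, control cohorts, truth log) are
first-class parts of the package.

Boundary convention: CNV boundaries are the positions of the first and
last supporting probe, and the estimated length is `end − start`.

## Worked example

```python
from pedcnvseg.fixture import run_fixture_pipeline

data, result = run_fixture_pipeline()
```

The reference cohort encodes eleven extended families carrying twelve
validated co-segregating CNVs. Running `python
examples/03_reference_cohort_pipeline.py` prints:

```
retained 12 candidates in 11 families (5 del, 7 dup)

type locus                          length family  freqEUR  DGV tier transmission  genes
del  chr1:45408389-45411073           2684  17545    0.012    4    3 maternal      ZSWIM5(intronic)
...
dup  chr7:8144894-8497305           352411  17122    0.000    0    1 both          ICA1(exonic-portion), NXPH1(exonic-portion)
dup  chr15:72538187-72549215         11028  17122    0.000    0    1 both          UBL7(exonic-portion)
```

Each row is one retained candidate: its boundaries and length, the
family carrying it, the European-ancestry control carrier frequency
(e.g. `0.012` = 9 of 727 controls), the catalogue count, the priority
tier, the inferred parental transmission route, and the gene context.
Family 17122 contributes two duplications carried by the same four
individuals, hence identical transmission labels. The carrier-vs-spouse
clinical comparison on this cohort gives the 2×2 table
[[12, 8], [6, 14]] and a two-sided Fisher exact p of 0.111
(`examples/05_statistics.py`).

The other example scripts cover interval matching (`01`), kinship and
transmission inference (`02`) and a simulated 42-family cohort checked
against its truth log (`04`). A thin CLI wraps the same library:

```sh
pedcnv-seg fixture --out out/           # reference cohort + report
pedcnv-seg simulate --seed 7 --out sim/ # synthetic cohort files
pedcnv-seg run --calls sim/calls.rawcnv --ped sim/families.ped \
    --controls sim/controls.tsv --dgv sim/dgv.tsv --out results/
pedcnv-seg stats fisher --table 12,8,6,14
```

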