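# Methods

## Model and rationale

The screen targets rare, dominantly inherited CNVs with incomplete
penetrance in extended multiplex families. Its discriminating signal is
identity by descent: for a non-inbred pair with kinship coefficient φ
the expected autosomal fraction shared IBD is 2φ — 0.5 for full
siblings, 0.25 for avuncular pairs, 0.125 for first cousins, 0.03125
for second cousins — so the probability that a private variant reaches
all affected members of an extended family by chance falls off rapidly
with relationship distance. Kinship is computed by the standard
recursion (φ(i,i) = ½(1 + φ(father, mother)); φ(i,j) = ½(φ(father_i, j)
+ φ(mother_i, j)), recursing on the individual further from the
founders; founders unrelated and non-inbred), with exact `Fraction`
arithmetic so closed-form values are reproduced without rounding. The
test suite checks it against an independent ancestral-path-counting
oracle on random pedigrees.

A locus survives the screen when

* every genotyped, QC-passed affected family member carries a
  type-matched call with ≥ 50% reciprocal overlap (the candidate
  interval is the intersection across those calls),
* at most one married-in individual carries it (two or more married-in
  carriers mean the variant entered the family more than once and
  cannot be IBD from one source),
* a single-origin descent explanation exists: some individual, not a
  typed non-carrier, reaches every known carrier through parent–child
  links passing only through carriers or genotype-unknown members, and
* its ancestry-matched control carrier frequency is < 1.5% (exact
  fraction comparison; the DGV-style catalogue count is annotated but
  never rejects, since well-catalogued loci can still be reported when
  rare in matched controls).

Unaffected blood-relative carriers are explicitly permitted — the model
is dominant with incomplete penetrance, and in practice such variants
pass through unaffected transmitting parents.

### Interpretive choices that the source analysis leaves open

* **"Overlapping by at least 50% of their lengths"** is read as
  reciprocal (both operands), the conservative and field-standard
  reading; a config switch (`overlap_mode: either`) provides the looser
  alternative.
* **"No clear segregation with affection status"** is operationalized
  as the single-origin descent test above; it is exposed as
  `require_single_origin` in the run configuration.
* **Boundary convention**: lengths are `end − start`, the span between
  the first and last supporting probe. This convention reproduces every
  published estimated length exactly from its printed boundaries, which
  is the package's evidence for it; whether coordinates are 0- or
  1-based is not asserted. BED input (0-based half-open) is converted
  on ingest to first/last covered position.
* **Transmission labels** are aggregated per affected carrier from the
  parent through whom the variant arrives under the chosen origin:
  all-maternal → `maternal`, all-paternal → `paternal`, mixed →
  `both`, any ambiguous route → `undetermined`. Ties among feasible
  origins are broken toward the most recent (deepest) one,
  deterministically by identifier; alternatives are kept in a
  diagnostics field.
* **Married-in classification**: the blood line is the founding couple
  (the parentless couple whose joint descendants include the most
  affected members) plus its descendants; parentless individuals
  outside it are married-in. Affected individuals stay in the affected
  partition regardless of lineage. A married-in who is also related to
  non-descendant blood members is flagged with a warning, not
  reclassified.
* **Review-zone samples** (0.3 < SDLRR < 0.4 and 100–300 CNVs, strict
  bounds on SDLRR and 100/300 inclusive) are retained with a logged
  flag because the original manual mosaicism review cannot be
  automated; `strict_qc` excludes them instead. SDLRR = 0.4 fails
  ("< 0.4" is the inclusion rule); SDLRR = 0.3 or 100 CNVs alone are
  outside the review zone.
* **Competing shared groups** at one locus (nested or staggered calls)
  are resolved as maximal cliques under the same-CNV predicate; when
  several cover the same affected set the longest intersection wins and
  the alternatives are logged.
* **Control carrier counting** is per distinct individual (a sample
  with two matching calls counts once). Displayed frequencies are
  rounded half-up to 3 decimals; threshold comparisons always use the
  exact fraction.

## Statistics

* **Fisher's exact test (two-sided)** uses point-probability summation:
  with margins fixed, p is the sum of hypergeometric point
  probabilities of all tables no more probable than the observed one
  (relative tolerance 1e-7; any zero margin gives p = 1). This is the
  convention under which the carrier-vs-spouse table [[12, 8], [6, 14]]
  yields p = 0.111; doubling-the-smaller-tail is not used. The suite
  verifies the implementation against exact-fraction enumeration for
  every 2×2 table with total ≤ 40.
* **Kruskal–Wallis** uses mid-ranks with the tie correction
  H' = H / (1 − Σ(t³ − t)/(N³ − N)) and a χ²(k−1) p-value (delegated to
  scipy's reference implementation); an exact permutation route is
  available for pooled N ≤ 10 where the asymptotic approximation is
  poor.
* **Carrier–spouse comparison**: unaffected carriers pooled over all
  retained candidates (counted once), paired with co-parent spouses who
  carry no candidate CNV of the family; carrier–carrier couples are
  excluded and logged. Rows carrier/spouse, columns
  any-diagnosis/none.

## The synthetic cohort generator

The generator states the study conditions as defaults: 42 extended
families (28 with two, 8 with three, 6 with four affected
cousin-or-more-distant relatives), a dominant planted risk CNV with
penetrance 0.6 and phenocopy rate 0.001 (the source analysis gives no
penetrance estimate; these are this package's stated configuration, and
penetrance 1.0 / phenocopy 0 are used where tests require determinism),
and a control cohort of 727 European-ancestry plus 111
African-American samples split over two recruiting centers. One family
is African-American, the rest European, matching the cohort the screen
was designed for.

Pedigree templates (avuncular pair, first/second cousin pair, three- and
four-affected extensions) have untyped founders and typed descendants
and spouses. Gene dropping is Mendelian with diploid bookkeeping:
founders receive alleles by designation (planted, one heterozygous
copy in a founder) or by carrier frequency (background; homozygous
carriers only via explicit `hom_rate`, reflecting their rarity), each
child inherits per parent with probability allele-count/2, and
affection is penetrance for carriers, phenocopy otherwise. Families
with a planted variant are resampled until the ascertainment condition
(all probands affected) holds — which reproduces the conditional
distribution given ascertainment. Families without a planted variant
have their probands set affected directly; resampling sporadic families
at phenocopy rate 0.001 would essentially never terminate and their
affection pattern carries no signal for the screen.

"Frequency" means carrier frequency throughout (founder assignment and
control draws), so the generator's binomial calibration oracle is
exactly Binomial(n, f). Boundary jitter is uniform within ± jitter bp
per boundary, capped at a fifth of the locus length so reciprocal
overlap with the locus definition always stays ≥ 50%. Emitted DGV-style
records are capped (default 50 per locus) because the pipeline
thresholds on presence, not magnitude. Every locus is written to a
truth log with its introducer, carrier set, transmission route and an
`expected_retained` verdict — the oracle for end-to-end tests.

What the generator does **not** emulate: raw array intensities (QC
metrics are drawn in the passing range, not computed), genotype-level
SNP data, ancestry admixture, de novo events, mosaicism, multi-allelic
loci, and call-boundary errors beyond uniform jitter. Passing
end-to-end tests therefore demonstrate the correctness of the screen's
logic under its stated model, not robustness to array-calling
artifacts.

## The reference cohort

`pedcnvseg.fixture` deterministically encodes the twelve validated
co-segregating CNVs (five deletions, seven duplications, eleven
families) with their published boundaries, per-cohort control carrier
counts (e.g. 9 of 727 European controls → 0.012) and catalogue counts
(">300" realized as 301). The drawn pedigrees of the original families
are not machine-readable, so every fixture family uses a canonical
first-cousin-pair topology that preserves the analysis surfaces
(carrier counts, lengths, frequencies, label identity for the
family-17122 pair); deletion families transmit through two blood-line
sisters (maternal labels), duplication families through a brother and a
sister (label `both`). Two transmitting mothers are DNA-unavailable so
exactly 20 genotyped unaffected carrier–spouse pairs exist, of whom 12
carriers and 6 spouses carry a clinical label, reproducing the
published 2×2 comparison. Gene models and literature regions are
synthetic stand-ins built so each locus reproduces its reported gene
context (e.g. the 13q31.1 deletion 153.5 kb upstream of *POU4F1*).

One internal inconsistency of the source is preserved rather than
reconciled: the narrative counts five loci absent from both controls
and catalogue, but the published table's 4p16.3 row is also 0/0/0, so
the pipeline reports six absent-everywhere loci (two of them tier 1 by
literature support, four tier 2).

## Problem sizes and determinism

All randomness flows through seeded `numpy` generators; cohort emission
is byte-deterministic per seed. Test problem sizes are chosen to keep
each suite comfortably within a desktop run: the Fisher enumeration
scans all ~150k tables with total ≤ 40, the kinship oracle sweeps 200
random pedigrees of ≤ 5 generations, sensitivity uses 120 fully
penetrant planted replicates across all five templates, parameter
recovery 50 replicates at penetrance 0.6 against an exhaustive
carrier-configuration enumeration, and the null-uniformity check of the
rank-sum p-values uses 2000 replicates of three groups of 25 (large
enough that the χ² approximation is accurate). `scripts/acceptance.py`
runs the reference cohort end to end plus 100 sensitivity replicates in
well under a minute.

## Known limitations

* Inbreeding loops are handled only as far as the kinship recursion's
  native behaviour; X-linked kinship is out of scope (the analysis is
  autosomal by design).
* The single-origin segregation test is a deliberate formalization of
  an informally stated exclusion rule; other operationalizations
  (e.g. counting unaffected carriers against a quota) would admit
  slightly different candidate sets.
* VCF symbolic-allele ingestion (`<DEL>`/`<DUP>`) is a possible
  extension, not implemented; inputs are PennCNV-style text, PED, TSV
  and BED.
* Candidate significance is not tested statistically — the screen is a
  prioritization funnel whose downstream validation was experimental,
  and per-candidate p-values would be miscalibrated under family
  ascertainment.
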