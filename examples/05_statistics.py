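"""The supporting statistics: exact 2x2 test and rank-sum comparison.

The carrier-vs-spouse comparison asks whether unaffected CNV carriers
have more psychiatric/developmental diagnoses than their non-carrier
spouses; with 12/20 carriers and 6/20 spouses diagnosed the two-sided
Fisher exact p is 0.111 - a trend, not significance.  The Kruskal-Wallis
rank-sum test compares per-sample CNV counts between groups (e.g. DNA
sources) without distributional assumptions.
"""

from pedcnvseg import ContingencyTable2x2, fisher_exact_two_sided, kruskal_wallis

table = ContingencyTable2x2(12, 8, 6, 14)
p = fisher_exact_two_sided(table)
print(f"carriers 12/20 vs spouses 6/20 diagnosed: two-sided Fisher p = {p:.3f}")

# perfect separation on tiny counts: only 2 of the 252 equally likely
# tables are as extreme
print(f"[[5,0],[0,5]]: p = {fisher_exact_two_sided(ContingencyTable2x2(5, 0, 0, 5)):.4f}")

h, p_kw = kruskal_wallis([[48, 52, 61, 55], [70, 66, 73, 80], [50, 58, 49, 62]])
print(f"CNV counts in three groups: H = {h:.3f}, chi-square p = {p_kw:.3f}")

h2, p_exact = kruskal_wallis([[1, 2, 3], [4, 5, 6]], exact=True)
print(f"tiny groups, exact permutation: H = {h2:.3f}, p = {p_exact:.3f}")
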