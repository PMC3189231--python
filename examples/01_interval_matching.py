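"""CNV identity: the 50% reciprocal-overlap rule.

Two CNV records are "the same CNV" when their types match and their
overlap covers at least half of *both* lengths.  This is what makes
control-cohort and catalogue filtering robust to small boundary
differences between array calls.
"""

from pedcnvseg import CNVCall, GenomicInterval, interval_length, is_same_cnv, overlap_bp

# a validated duplication and a slightly shifted call of the same event
a = CNVCall("patient", GenomicInterval("7", 8144894, 8497305), 3, 352)
b = CNVCall("control", GenomicInterval("7", 8150000, 8500000), 3, 340)

ov = overlap_bp(a.interval, b.interval)
print(f"lengths: {interval_length(a.interval)} and {interval_length(b.interval)} bp")
print(f"overlap: {ov} bp "
      f"({ov / interval_length(a.interval):.1%} of a, {ov / interval_length(b.interval):.1%} of b)")
print("same CNV (reciprocal >= 50%):", is_same_cnv(a, b))

# a nested call covering only a quarter of the other fails the rule
c = CNVCall("other", GenomicInterval("7", 8144894, 8233000), 3, 90)
print("nested short call vs a:", is_same_cnv(a, c),
      "- the overlap is all of c but only",
      f"{overlap_bp(a.interval, c.interval) / interval_length(a.interval):.1%} of a")

# type-mismatched records never match, whatever the overlap
d = CNVCall("x", GenomicInterval("7", 8144894, 8497305), 1, 352)
print("del vs dup at identical coordinates:", is_same_cnv(a, d))
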