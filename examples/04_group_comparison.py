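"""Compare event counts between knockout groups with exact rank-sum tests.

Counts alterations per sample from the bundled (synthetic) supplementary-
style segment file, then tests each knockout group against the wild type
with the exact two-sided Wilcoxon rank-sum test and Holm adjustment —
the W and p values reported alongside such passaging studies.
"""

from cnaevo import read_segment_file
from cnaevo.stats import compare_groups

segments = read_segment_file("tests/data/synthetic_supplementary_segments.tsv")
counts_by_group: dict[str, list[float]] = {}
for sample, segs in segments.items():
    group = sample.split("_")[0]
    n = sum(1 for s in segs if s.call not in ("neutral", ""))
    counts_by_group.setdefault(group, []).append(n)

print("events per sample, by group:")
for group, counts in counts_by_group.items():
    print(f"  {group:7s} {counts}")

pairs = [("TP53", "CDKN2A"), ("TP53", "RB1"), ("CDKN2A", "RB1")]
print("\npairwise rank-sum comparisons (W = rank-sum of the first group):")
for r in compare_groups(counts_by_group, pairs):
    mode = "exact" if r.exact_flag else "normal approx."
    print(f"  {r.group1} vs {r.group2}: W={r.w:.0f}  p={r.p_two_sided:.4f}  "
          f"Holm-adjusted p={r.p_holm:.4f}  ({mode})")
print("\nA small Holm-adjusted p flags a genuine difference in alteration"
      "\nburden between regimes; with n=3 per group the smallest attainable"
      "\nexact two-sided p is 0.1, so these comparisons are illustrative.")
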