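"""Two-group LFQ comparison with permutation FDR.

Simulates a 3v3 label-free experiment (1,000 proteins spanning several
orders of magnitude, 50 planted 4-fold differential proteins, 15%
replicate CV, low-abundance missingness), then runs the full Fig-2-style
analysis: replicate presence intersection, dynamic-range ranking,
Welch-t permutation-FDR differential test (fold change >= 2, FDR 0.05)
and z-scored hierarchical clustering of the significant proteins.
"""

import netome
from netome import evaluate

lfq, truth = netome.simulate_lfq(netome.SyntheticLFQSpec(seed=7))

venn = netome.detect_common(lfq)
print(f"common in all 3 replicates: {venn['n_common']}")
print(f"intersection of the two groups: {venn['n_intersection']}")

rank = netome.dynamic_range(lfq,
                            reference_list=[p for p, _ in
                                            truth.differential_proteins])
print(f"dynamic range: {rank.attrs['span_orders']:.2f} orders of magnitude")

result = netome.differential_test(lfq, fc_cutoff=2.0, fdr_level=0.05, seed=7)
n_sig = int(result["significant"].sum())
score = evaluate.score_proteomics(result, truth.differential_proteins)
print(f"significant proteins (|FC| >= 2, q <= 0.05): {n_sig} "
      f"of {len(result)} tested")
print(f"sensitivity vs planted truth: {score['sensitivity']:.2f}  "
      f"realized FDP: {score['false_discovery_proportion']:.3f}")

cluster = netome.zscore_cluster(lfq, result.index[result["significant"]])
print(f"cluster leaf order (first 5): {cluster['leaf_order'][:5]}")
# most planted 4-fold proteins are recovered with no false discoveries;
# the heatmap row order comes from average-linkage clustering of the
# z-scored log2 intensities
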