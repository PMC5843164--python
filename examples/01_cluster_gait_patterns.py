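"""Cluster a synthetic HSP cohort into sagittal gait patterns.

Generates a 12-subject cohort with known planted patterns, computes the
multivariate DTW dissimilarity over the five sagittal channels, builds the
average-linkage dendrogram, cuts it into 7 groups (6 patterns + outlier)
and compares the recovered labels with the planted ground truth.
"""

from sklearn.metrics import adjusted_rand_score

import gaitpheno as gp

cycles, records, truth = gp.generate_cohort(gp.CohortConfig(n_subjects=12, seed=0))
print(f"{len(cycles)} cycles from {len(records)} subjects")

dm = gp.distance_matrix(cycles)                 # DTW over the sagittal channels
dendro = gp.average_linkage(dm)
assignment = gp.cut_dendrogram(dendro, k=7)
summary = gp.pattern_summary(assignment, cycles)

print("\nCluster sizes (pattern 1 = largest):")
print(summary["clusters"].to_string(index=False))
print("\nPer-subject pattern usage:")
print(summary["usage_counts"].to_string(index=False))

planted = truth.set_index("cycle_id").loc[assignment.table["cycle_id"], "pattern"]
ari = adjusted_rand_score(planted, assignment.table["pattern"])
print(f"\nAdjusted Rand index vs planted labels: {ari:.3f}")
print("(1.0 means the flat cut reproduces the planted partition exactly;")
print(" values above ~0.9 indicate near-perfect pattern recovery.)")
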