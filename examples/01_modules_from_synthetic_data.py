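"""Detect coexpression modules in a synthetic High/Low expression pair.

Generates three planted 40-transcript modules (factor model, mean loading
0.7), builds the unsigned beta=10 adjacency for each condition, averages
them into a consensus network, detects modules by dendrogram cutting with
eigengene merging, and validates them against random transcript sets.
"""

import pandas as pd
from sklearn.metrics import adjusted_rand_score

import coexdisrupt as cd

bundle = cd.simulate_expression_pair(disruption_fraction=0.0, seed=42)
adj_high = cd.build_adjacency(bundle.expr_high, beta=10)
adj_low = cd.build_adjacency(bundle.expr_low, beta=10)
consensus = cd.consensus_adjacency([adj_high, adj_low])

combined = cd.ExpressionMatrix(
    pd.concat([bundle.expr_high.values, bundle.expr_low.values], axis=1)
)
partition = cd.detect_modules(consensus, combined, min_module_size=30)
pvals = cd.validate_modules(consensus, partition, n_perm=500, seed=1)

print("detected module sizes:", partition.sizes())
print("validation p-values (density vs random sets):")
print(pvals.round(4).to_string())
ari = adjusted_rand_score(bundle.truth_partition, partition.assignment)
print(f"adjusted Rand index vs planted truth: {ari:.3f}")
print("scale-free fit R^2 (High):", round(cd.scale_free_fit(adj_high), 3))
# ARI 1.0 means the planted modules were recovered exactly; small validation
# p-values mean random transcript sets of the same size almost never reach
# each module's internal density (0.002 = 1/501 is the smallest reportable).
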