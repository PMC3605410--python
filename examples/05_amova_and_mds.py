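"""Genome-wide genetic differentiation between selected lines.

Encodes each genome as a 0/1/2 dosage vector, computes pairwise Manhattan
distances, partitions them into among- vs within-group sums of squares
(AMOVA) with a permutation F-test, and embeds the samples in 2-D with
classical (Torgerson) multidimensional scaling.
"""

import numpy as np

import coexdisrupt as cd

bundle = cd.simulate_genotypes(
    n_founders=8, n_markers=500, n_intervals=25, n_samples_per_group=40,
    shift_strength=0.8, n_shifted_intervals=3, seed=3,
)
res = cd.amova(bundle.genotypes, n_perm=999, seed=11)
print(f"AMOVA F = {res.f_statistic:.2f}, permutation p = {res.p_value:.4g}")
print(f"SS among groups = {res.ss_among:.0f}, within = {res.ss_within:.0f}")

coords = cd.mds_embed(cd.manhattan_distances(bundle.genotypes), k=2)
groups = bundle.genotypes.group.to_numpy()
for g in ("High", "Low"):
    centroid = coords[groups == g].mean(axis=0)
    print(f"{g} centroid in MDS space: ({centroid[0]:.1f}, {centroid[1]:.1f})")
# A significant F with well-separated MDS centroids shows selection fixed
# different founder alleles in the two lines at the shifted intervals.
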