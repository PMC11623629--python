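"""Behavioral multiple-arrangements: subset design, simulation, aggregation.

Designs pair-covering stimulus subsets, simulates a participant arranging
them according to a planted dissimilarity structure, aggregates the sparse
screen distances into a behavioral RDM, and checks how well the planted
geometry is recovered.
"""

import numpy as np

import repgeom as rg

rng = np.random.default_rng(0)

# planted "psychological space": 20 stimuli in 2-D, so the arena can
# represent it exactly and the noiseless round trip is perfect
pts = rng.normal(size=(20, 2)) * 60
d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
planted = rg.RDM(d, tuple(f"clip{i:02d}" for i in range(20)))

design = rg.design_subsets(list(planted.labels), n_subsets=4, subset_size=8,
                           n_candidates=200, seed=1)
total_pairs = 20 * 19 // 2
print(f"subset design: {design.n_subsets} subsets of {design.subset_size}; "
      f"subsets alone cover {design.unique_pair_count}/{total_pairs} pairs "
      f"(the full-set arrangement guarantees the rest)")

for jitter in (0.0, 15.0):
    records = rg.simulate_arrangement_session(planted, design,
                                              jitter_sd=jitter, seed=2)
    behavioral = rg.aggregate_arrangements(records, labels=planted.labels)
    rho = rg.spearman_fit(behavioral, planted)
    print(f"jitter {jitter:4.0f} px -> {len(records)} records, "
          f"Spearman(aggregated, planted) = {rho:.3f}")

coords = rg.mds_embed(rg.aggregate_arrangements(
    rg.simulate_arrangement_session(planted, design, jitter_sd=0.0, seed=2),
    labels=planted.labels), 2)
print(f"2-D MDS embedding of the aggregated RDM: {coords.shape[0]} points, "
      f"for visualization of the recovered configuration")
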