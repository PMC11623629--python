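"""Fit candidate models to a simulated neighborhood and test them.

Simulates two-session response patterns whose geometry mixes a dominant
category model with weak competitors, builds each subject's split-data
RDM, and runs the full model-comparison stack: per-model Spearman fits
with sign-flip permutation, joint R² with the re-centered bootstrap,
variance partitioning, and the intersubject noise ceiling.
"""

import numpy as np

import repgeom as rg

truth = rg.GroundTruth(
    n_subjects=10, n_categories=6, n_exemplars=3,
    n_units_per_neighborhood=150, noise_sd=0.7,
    mixture_weights={"roi": (0.7, 0.15, 0.15)},
    seed=4,
)
stimuli = truth.stimuli()
models = rg.simulate_model_rdms(stimuli, truth)
names = [m.meta["name"] for m in models]
pairs = rg.simulate_subject_patterns(truth, "roi", model_rdms=models)
rdms = [rg.splitdata_rdm(s1, s2) for s1, s2 in pairs]
print(f"{len(rdms)} subjects x {rdms[0].n} conditions, planted weights "
      f"{truth.mixture_weights['roi']} over {names}")

for name, model in zip(names, models):
    rhos = np.array([rg.spearman_fit(r, model) for r in rdms])
    test = rg.signflip_permutation_test(rhos, n_perms=2000, seed=4)
    print(f"  {name:18s} group rho = {test.observed:+.3f}  "
          f"sign-flip p = {test.p_value:.4f}")

r2s = np.array([rg.joint_fit(r, models) for r in rdms])
boot = rg.recentered_bootstrap_test(r2s, n_boot=2000, seed=4)
isc = rg.isc_noise_ceiling(rdms)
print(f"joint R² = {boot.observed:.3f} (bootstrap p = {boot.p_value:.4f}); "
      f"noise ceiling r = {isc.group_mean:.3f}")
print(f"-> the joint model explains "
      f"{rg.ceiling_fraction(boot.observed, isc.group_mean):.0f}% of the "
      f"ceiling-indexed meaningful variance")

named = dict(zip(names, models))
uniq = {n: np.mean([
    rg.variance_partition(r, named, [[n]]).unique_r2[n] for r in rdms
]) for n in names}
print("mean unique R² per model (full - nested):",
      {k: round(v, 4) for k, v in uniq.items()})
print("-> the planted dominant model carries the unique variance")
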