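"""Run the end-to-end neighborhood pipeline on synthetic data.

One call simulates every neighborhood's patterns from planted mixture
weights, builds split-data RDMs through the neighborhood-map machinery,
fits all models per subject, partitions variance, computes noise ceilings,
and attaches sign-flip/bootstrap/FDR statistics. The result bundle is a
pure function of (ground truth, config) and writes to plain-text tables.
"""

import tempfile
from pathlib import Path

import repgeom as rg

truth = rg.GroundTruth(
    n_subjects=8, n_units_per_neighborhood=120, noise_sd=0.6,
    mixture_weights={
        "lateral_occipital": (1.0, 0.15, 0.15),   # category-dominated
        "early_visual":      (0.15, 0.15, 1.0),   # unstructured geometry
    },
    seed=9,
)
cfg = rg.AnalysisConfig(n_perms=1000, n_boot=1000, seed=9)
bundle = rg.run_pipeline(truth, cfg)

print("per-model group fits (sign-flip p, map-wise FDR q):")
print(bundle.model_fits.to_string(index=False))
print("\njoint fits with noise ceiling:")
cols = ["neighborhood", "joint_r2", "p", "isc_ceiling_r", "ceiling_fraction_pct"]
print(bundle.joint_fits[cols].to_string(index=False))
print("\nunique variance per partition:")
print(bundle.partitions.to_string(index=False))

out = Path(tempfile.mkdtemp()) / "bundle"
bundle.write(out)
print(f"\nbundle written to {out} "
      f"({sorted(p.name for p in out.iterdir())})")
print("re-running with the same truth/config reproduces these tables "
      "bitwise — the pipeline is a pure function of (truth, config, seed).")
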