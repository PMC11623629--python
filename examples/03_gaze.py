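"""Gaze trajectories: preprocessing, gaze RDMs, and reliability screening.

Simulates a small eye-tracking session (4 blocks, one trial per stimulus,
occasional blinks), preprocesses each trial (blink interpolation, 84 ms
median filter, decimation to 60 frames), builds one gaze RDM per block,
and screens the participant by inter-block reliability.
"""

import repgeom as rg

stimuli = rg.make_stimulus_set(6, 3)  # 18 stimuli keeps this quick
trials = rg.simulate_gaze_session(stimuli, n_blocks=4, blink_rate=0.15, seed=0)
print(f"simulated {len(trials)} trials of {trials[0].n_samples} samples "
      f"(1000 Hz x 2.5 s)")

by_block: dict[int, dict] = {}
n_blinky = 0
for t in trials:
    n_blinky += not t.valid.all()
    by_block.setdefault(t.block_index, {})[t.stimulus_id] = rg.gaze_preprocess(t)
out = next(iter(by_block[0].values()))
print(f"{n_blinky} trials contained a blink span; after preprocessing every "
      f"trial has {out.n_samples} valid samples (one per 24 Hz frame)")

block_rdms = [rg.gaze_rdm(by_block[b]) for b in sorted(by_block)]
retained, group_rdm, rel = rg.gaze_reliability_screen({"p00": block_rdms},
                                                      threshold=0.1)
print(f"inter-block gaze-RDM reliability: r = {rel['p00']:.3f} "
      f"(threshold .1 -> participant {'retained' if retained else 'dropped'})")
print(f"group gaze RDM: {group_rdm.n} x {group_rdm.n}, mean dissimilarity "
      f"{group_rdm.vector().mean():.0f} px summed over 60 frames")
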