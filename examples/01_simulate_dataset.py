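"""Generate a synthetic breath-hold session with known ground truth.

Writes a complete single-subject bundle — 4-D BOLD, tissue masks, events,
capnograph trace, motion table, and the true CVR/lag volumes — that the
rest of the examples analyze.
"""

from pathlib import Path

from bhcvr.io import SimulateConfig, simulate_dataset, write_simulation

out = Path("scratch/example_sim")
cfg = SimulateConfig(seed=7, shape=(20, 20, 10))
paths = write_simulation(out, cfg)

bold, truth, capno, paradigm = simulate_dataset(cfg)
print(f"paradigm: {paradigm.n_trials} holds of {paradigm.hold_duration:.0f} s, "
      f"{paradigm.total_duration:.0f} s total -> {bold.n_volumes} volumes at "
      f"TR {bold.tr} s")
print(f"tissue voxels: GM {truth.gm_mask.sum()}, WM {truth.wm_mask.sum()} "
      f"(true CVR {cfg.gm_cvr} / {cfg.wm_cvr} %/mmHg)")
print(f"capnograph: {capno.peak_times.size} end-tidal peaks, "
      f"baseline {cfg.baseline_petco2} mmHg, BH rise {cfg.delta_petco2} mmHg")
print("written:")
for key, path in paths.items():
    print(f"  {key:<12} {path}")
# The files emulate what a scanner + capnograph session would produce; the
# ground-truth volumes let every later estimate be checked against the truth.
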