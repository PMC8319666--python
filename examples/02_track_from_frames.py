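"""Render a synthetic session to images, then track the worm back out.

Each frame shows a single bright disk at the animal's true centroid; the
tracker thresholds the frame, keeps the largest blob and takes its
intensity-weighted centroid. On noiseless renders the recovered track
stays well within half a pixel of the truth.
"""

import numpy as np

import wormstates as ws

cfg = ws.SimulationConfig(duration_s=300.0, arena_px=(160, 160), seed=2)
states = ws.simulate_state_sequence(cfg)
truth = ws.simulate_track(states, cfg)
stack = ws.render_frames(truth, cfg)

track = ws.build_track(stack, cfg.frame_rate_hz, "demo",
                       threshold_method="fixed", fixed_threshold=100)
err = np.linalg.norm(track.positions - truth.positions, axis=1)

print(f"frames tracked : {int(track.valid.sum())}/{track.valid.size}")
print(f"centroid error : mean {err.mean():.3f} px, max {err.max():.3f} px")
print()
print("Sub-0.5 px errors mean per-frame speeds -- displacement between")
print("consecutive centroids -- are dominated by the worm, not the tracker.")
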