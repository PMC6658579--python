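"""The self-feeding loop: stage-2 output becomes the next stage-1 input.

With a stationary component the alternation contracts to a fixed point;
per-cycle changes shrink geometrically.
"""

import numpy as np

from fitloop import InversionConfig, LoopConfig, make_component, run_internal_dialogue

comp = make_component({"m": 2, "n": 2, "cond_cap": 100.0}, seed=1)
cfg = LoopConfig(mode="internal_dialogue", inversion=InversionConfig(gain=50.0))

trace = run_internal_dialogue(comp, np.array([0.5, -0.2]), 200, cfg)
hats = [r["u_hat"] for r in trace.records]
for c in (1, 10, 50, 100, 199):
    change = np.linalg.norm(hats[c] - hats[c - 1])
    print(f"cycle {c:3d}: |u_hat change| = {change:.3e}")

print()
print("The change decays geometrically: the internal dialogue settles on a")
print("self-consistent signal that survives the estimate/invert round trip.")
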