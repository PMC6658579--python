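"""Sender-receiver communication of an internal estimate.

The sender cannot transmit its estimate x directly; it inverts its own
estimator to get a sensorimotor-space signal u_hat, sends it through a
noisy channel, and the receiver reconstructs x' with its own similar
estimator.
"""

import numpy as np

from fitloop import (
    Agent,
    ChannelConfig,
    EstimatorBank,
    InversionConfig,
    LoopConfig,
    make_component,
    perturb_agent,
    run_dialogue,
    stream,
)

comp = make_component({"m": 3, "n": 3, "cond_cap": 10.0}, seed=1)
sender = Agent(
    bank=EstimatorBank(components=(comp,)),
    loop=LoopConfig(inversion=InversionConfig(gain=1e5, max_iter=50_000)),
)

for noise in (0.0, 0.1, 0.3):
    receiver = perturb_agent(sender, 0.02, stream(0, "mismatch"))
    trace = run_dialogue(
        sender,
        receiver,
        ChannelConfig(noise_sd=noise),
        6,
        stream(0, "chan"),
        u_init=np.array([0.8, -0.4, 0.5]),
    )
    errs = [r["reconstruction_error"] for r in trace.records]
    print(f"channel noise sd {noise:.1f}: median reconstruction error "
          f"{np.median(errs):.2e}")

print()
print("With a clean channel the receiver recovers the sender's estimate")
print("almost exactly; channel noise degrades the reconstruction smoothly.")
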