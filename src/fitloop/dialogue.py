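"""Sender–receiver communication of fitness-estimate components.

The sender cannot transmit its internal estimate x_i directly: only
signals in sensorimotor space can cross between organisms.  It therefore
inverts its own estimator to produce û_i = X̄_i x_i, a signal living in
the sensed-input space, and transmits that.  The receiver applies its own
similar estimator X'_i to the (possibly attenuated, noisy) received
signal u'_i, reconstructing x'_i ≈ x_i.  The reconstruction error is
bounded by three separable contributions: finite inversion gain, channel
degradation, and sender/receiver operator mismatch.

``run_dialogue`` alternates the roles: each turn the speaker runs its
two-stage loop on its latest input and transmits û; the listener
reconstructs and replies on the next turn using the received signal as
its own stage-1 input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .estimator import (
    EstimatorBank,
    EstimatorComponent,
    apply_component,
    clip_condition,
)
from .loop import LoopBuffers, LoopConfig, run_stage1, run_stage2

__all__ = [
    "Agent",
    "ChannelConfig",
    "DialogueTrace",
    "perturb_agent",
    "transmit",
    "receive",
    "run_dialogue",
]


@dataclass(frozen=True)
class Agent:
    """One conversational agent: an estimator bank plus its loop settings."""

    bank: EstimatorBank
    loop: LoopConfig = field(default_factory=LoopConfig)
    role: str = "sender"

    def __post_init__(self) -> None:
        if self.role not in ("sender", "receiver"):
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def component(self) -> EstimatorComponent:
        """The single component used in dialogue scenarios."""
        return self.bank.components[0]


@dataclass(frozen=True)
class ChannelConfig:
    """Transmission channel: multiplicative attenuation plus additive noise."""

    noise_sd: float = 0.0
    gain_loss: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0 < self.gain_loss <= 1):
            raise ValueError("gain_loss must lie in (0, 1]")


@dataclass
class DialogueTrace:
    """Per-turn records of an alternating dialogue."""

    records: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "turn": r["turn"],
                    "speaker": r["speaker"],
                    "reconstruction_error": r["reconstruction_error"],
                    "converged": r["converged"],
                    "flagged": r["flagged"],
                }
                for r in self.records
            ]
        )


def _perturb_component(
    comp: EstimatorComponent, delta: float, rng: np.random.Generator
) -> EstimatorComponent:
    if delta == 0.0:
        return comp
    # Zero-mean entry noise scaled so the relative parameter RMS change is
    # approximately delta: sd per entry = delta * ||P||_F / sqrt(count).
    def jitter(P: np.ndarray) -> np.ndarray:
        norm = float(np.linalg.norm(P))
        if norm == 0.0:
            norm = 1.0
        sd = delta * norm / np.sqrt(P.size)
        return P + sd * rng.standard_normal(P.shape)

    A = clip_condition(jitter(comp.A), comp.cond_cap)
    b = jitter(comp.b)
    return replace(comp, A=A, b=b, A_ref=A.copy(), b_ref=b.copy())


def perturb_agent(agent: Agent, delta: float, rng: np.random.Generator) -> Agent:
    """A similar-but-not-identical copy of an agent.

    Models the receiver owning its own version of the sender's estimator:
    every component parameter gets zero-mean noise with relative RMS size
    delta; delta = 0 returns a parameter-identical copy.  The condition
    cap is re-enforced.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    comps = tuple(_perturb_component(c, delta, rng) for c in agent.bank.components)
    bank = replace(agent.bank, components=comps)
    return replace(agent, bank=bank)


def transmit(
    u_hat: np.ndarray, channel: ChannelConfig, rng: np.random.Generator
) -> np.ndarray:
    """Send û through the channel: u' = gain_loss·û + noise."""
    u = channel.gain_loss * np.asarray(u_hat, dtype=float)
    if channel.noise_sd > 0:
        u = u + channel.noise_sd * rng.standard_normal(u.shape)
    return u


def receive(agent: Agent, u_prime: np.ndarray) -> np.ndarray:
    """Reconstruct x' by applying the receiver's own estimator to u'."""
    return apply_component(agent.component, np.asarray(u_prime, dtype=float))


def run_dialogue(
    sender: Agent,
    receiver: Agent,
    channel: ChannelConfig,
    n_turns: int,
    rng: np.random.Generator,
    u_init: np.ndarray | None = None,
) -> DialogueTrace:
    """Alternating dialogue between two agents.

    Turn t: the current speaker runs stage 1 on its latest input and
    stage 2 to produce û, transmits it, and the listener reconstructs
    x' = X' u'.  The received u' becomes the listener's stage-1 input on
    its next turn.  Components drift between turns at their configured
    slow timescale.  A diverged inversion flags the turn and the dialogue
    continues with held buffers.
    """
    if n_turns < 1:
        raise ValueError("n_turns must be >= 1")
    agents = [sender, receiver]
    buffers = [LoopBuffers(), LoopBuffers()]
    if u_init is None:
        u_init = np.ones(sender.component.m)
    inputs: list[np.ndarray | None] = [np.asarray(u_init, dtype=float), None]
    trace = DialogueTrace()
    from .estimator import drift_parameters  # local import avoids cycle at top

    for turn in range(n_turns):
        s = turn % 2
        r = 1 - s
        speaker, listener = agents[s], agents[r]
        u_in = inputs[s]
        if u_in is None:  # listener has heard nothing yet; should not happen
            u_in = np.zeros(speaker.component.m)
        comp = speaker.component
        buffers[s] = run_stage1(comp, u_in, buffers[s])
        buffers[s], result = run_stage2(comp, buffers[s], speaker.loop.inversion)
        flagged = result.diverged or buffers[s].u_buf is None
        if flagged:
            u_hat = np.zeros(comp.m) if buffers[s].u_buf is None else buffers[s].u_buf
        else:
            u_hat = buffers[s].u_buf
        u_prime = transmit(u_hat, channel, rng)
        x_prime = receive(listener, u_prime)
        x_true = buffers[s].x_buf
        denom = max(float(np.linalg.norm(x_true)), 1e-300)
        err = float(np.linalg.norm(x_prime - x_true)) / denom
        trace.records.append(
            {
                "turn": turn,
                "speaker": "sender" if s == 0 else "receiver",
                "u_hat": np.array(u_hat, copy=True),
                "u_prime": np.array(u_prime, copy=True),
                "x_prime": np.array(x_prime, copy=True),
                "reconstruction_error": err,
                "converged": result.converged,
                "flagged": bool(flagged),
            }
        )
        inputs[r] = u_prime  # the reply grows from what was heard
        for i in (0, 1):
            c = agents[i].component
            if c.drift_sd > 0:
                drifted = drift_parameters(c, agents[i].loop.cycle_period, rng)
                bank = replace(
                    agents[i].bank,
                    components=(drifted,) + agents[i].bank.components[1:],
                )
                agents[i] = replace(agents[i], bank=bank)
    return trace
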