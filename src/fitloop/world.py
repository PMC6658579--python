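"""The world process: hidden state w, fitness landscape F, and sensing.

The effective world ``w`` is split into the organism's *form* ``theta``
(the part the organism can change) and an *environment* vector ``env``
that drifts as a mean-reverting (Ornstein–Uhlenbeck) process.  Fitness is
a smooth multi-peak landscape over form space: a sum of Gaussian bumps,
optionally gated by a positive function of the environment.  Sensing
projects (theta, env) into the organism's input space with additive
Gaussian observation noise.

The landscape is a modelling choice: the underlying theory leaves the
fitness operator nonlinear, nonstationary and otherwise unspecified.  A
bump landscape is the simplest smooth, non-negative, multi-peak family
that exercises the variance-modulated drift mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Bump",
    "WorldConfig",
    "WorldState",
    "FitnessValue",
    "init_world",
    "step_environment",
    "evaluate_fitness",
    "sense",
]


@dataclass(frozen=True)
class Bump:
    """One Gaussian fitness peak over form space."""

    center: tuple[float, ...]
    height: float
    width: float

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("bump height must be positive")
        if self.width <= 0:
            raise ValueError("bump width must be strictly positive")


@dataclass(frozen=True)
class WorldConfig:
    """Static description of the world process.

    Parameters
    ----------
    dim_form
        Dimension of the organism's form vector theta.
    dim_env
        Dimension of the environment vector (0 = no environment).
    landscape
        Gaussian bumps defining the fitness landscape over theta-space.
    env_timescale
        Mean-reversion time constant of the environment walk, in time
        units.  ``inf`` freezes the environment.
    env_sd
        Stationary standard deviation of each environment coordinate.
    obs_noise_sd
        Standard deviation of additive sensing noise.
    dt
        Fast simulation time step.
    init_scale
        Standard deviation of the initial theta draw.
    env_gate
        Gating strength: fitness is multiplied by exp(env_gate * mean(env)),
        a smooth positive factor.  0 disables gating.
    """

    dim_form: int
    dim_env: int = 0
    landscape: tuple[Bump, ...] = field(default_factory=tuple)
    env_timescale: float = 100.0
    env_sd: float = 1.0
    obs_noise_sd: float = 0.0
    dt: float = 0.01
    init_scale: float = 1.0
    env_gate: float = 0.0

    def __post_init__(self) -> None:
        if self.dim_form < 1:
            raise ValueError("dim_form must be a positive integer")
        if self.dim_env < 0:
            raise ValueError("dim_env must be non-negative")
        if not self.landscape:
            raise ValueError("landscape needs at least one bump")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.env_timescale <= 0:
            raise ValueError("env_timescale must be positive")
        if self.obs_noise_sd < 0:
            raise ValueError("obs_noise_sd must be non-negative")
        for b in self.landscape:
            if len(b.center) != self.dim_form:
                raise ValueError("bump center dimension must equal dim_form")

    @property
    def sense_dim(self) -> int:
        """Dimension of the sensed vector u = (theta, env) + noise."""
        return self.dim_form + self.dim_env


@dataclass(frozen=True)
class WorldState:
    """Instantaneous world state: organism form, environment, clock."""

    theta: np.ndarray
    env: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.theta)) and np.all(np.isfinite(self.env))):
            raise ValueError("world state entries must be finite")


@dataclass(frozen=True)
class FitnessValue:
    """Scalar fitness plus its per-bump component vectors."""

    f: float
    components: tuple[np.ndarray, ...]


def init_world(config: WorldConfig, seed: int) -> WorldState:
    """Draw the initial world state.

    theta ~ N(0, init_scale^2 I); environment starts at zero; t = 0.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    theta = config.init_scale * rng.standard_normal(config.dim_form)
    env = np.zeros(config.dim_env)
    return WorldState(theta=theta, env=env, t=0.0)


def step_environment(
    state: WorldState, config: WorldConfig, rng: np.random.Generator
) -> WorldState:
    """Advance the environment one dt by its mean-reverting walk.

    Euler–Maruyama step of de = -(e/tau) dt + env_sd * sqrt(2 dt / tau) xi,
    whose stationary standard deviation is env_sd (up to O(dt/tau)).
    theta is untouched; time advances by dt.  An infinite timescale or
    dim_env = 0 leaves the environment unchanged.
    """
    env = state.env
    if config.dim_env > 0 and np.isfinite(config.env_timescale):
        a = config.dt / config.env_timescale
        noise = config.env_sd * np.sqrt(2.0 * a) * rng.standard_normal(config.dim_env)
        env = env * (1.0 - a) + noise
    return replace(state, env=env, t=state.t + config.dt)


def evaluate_fitness(state: WorldState, config: WorldConfig) -> FitnessValue:
    """Evaluate the landscape at the current form.

    Each bump j contributes height_j * exp(-||theta - c_j||^2 / (2 w_j^2)),
    gated by exp(env_gate * mean(env)) when gating is on.  Components are
    the per-bump contributions; the scalar f is their sum (monotone
    pooling, non-negative by construction).  Purely deterministic.
    """
    gate = 1.0
    if config.env_gate != 0.0 and state.env.size > 0:
        gate = float(np.exp(config.env_gate * float(np.mean(state.env))))
    contribs = []
    for b in config.landscape:
        d2 = float(np.sum((state.theta - np.asarray(b.center)) ** 2))
        contribs.append(np.array([gate * b.height * np.exp(-d2 / (2.0 * b.width**2))]))
    f = float(sum(c[0] for c in contribs))
    return FitnessValue(f=f, components=tuple(contribs))


def sense(
    state: WorldState, config: WorldConfig, rng: np.random.Generator
) -> np.ndarray:
    """Sensed input u: the (theta, env) projection plus observation noise.

    With obs_noise_sd = 0 the projection is returned exactly.
    """
    u = np.concatenate([state.theta, state.env])
    if config.obs_noise_sd > 0:
        u = u + config.obs_noise_sd * rng.standard_normal(u.shape)
    return u
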