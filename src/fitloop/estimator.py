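"""The fitness estimator bank: components x_i = X_i u_i and their drift.

Each component is a forward-evaluable nonlinear map phi(A u + b) with a
strictly increasing coordinatewise nonlinearity phi.  Two kinds exist:

* ``linear_monotone`` — the structured family; invertible on its range
  whenever A is square and full rank, which makes an exact analytic
  inverse available *for testing* (see :mod:`fitloop.inversion`).
* ``blackbox`` — same map, but consumers are only entitled to forward
  evaluation; the feedback-inversion loop is then the sole inversion path.

Components drift slowly: every parameter entry follows a mean-reverting
random walk around its construction-time value, with a timescale far
above the fast step, so the operator is nonstationary but locally frozen.
The scalar estimate x aggregates component outputs through a weighted sum
of their means followed by a non-negative squashing map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Mapping

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "EstimatorComponent",
    "EstimatorBank",
    "NONLINEARITIES",
    "OUTPUT_MAPS",
    "make_component",
    "apply_component",
    "aggregate_estimate",
    "drift_parameters",
    "clip_condition",
]

_SOFTPLUS_FLOOR = 0.2  # lower bound on the slope of the default nonlinearity


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def _softplus_floor(z: np.ndarray) -> np.ndarray:
    # softplus plus a linear floor: strictly increasing, bijective on R,
    # slope in (floor, 1 + floor) — invertible and well conditioned.
    return _softplus(z) + _SOFTPLUS_FLOOR * z


def _softplus_floor_inv(y: np.ndarray) -> np.ndarray:
    y = np.atleast_1d(np.asarray(y, dtype=float))
    out = np.empty_like(y)
    for i, yi in enumerate(y.ravel()):
        lo, hi = -1.0, 1.0
        while _softplus_floor(np.array(lo)) > yi:
            lo *= 2.0
        while _softplus_floor(np.array(hi)) < yi:
            hi *= 2.0
        out.ravel()[i] = brentq(
            lambda z: float(_softplus_floor(np.array(z))) - yi, lo, hi, xtol=1e-14
        )
    return out


#: name -> (phi, phi_inverse); every phi is strictly increasing on R.
NONLINEARITIES: Mapping[str, tuple[Callable, Callable]] = {
    "identity": (lambda z: z, lambda y: y),
    "softplus_floor": (_softplus_floor, _softplus_floor_inv),
}

#: name -> smooth non-negative scalar squashing for the aggregate estimate.
OUTPUT_MAPS: Mapping[str, Callable[[float], float]] = {
    "softplus": lambda s: float(np.logaddexp(0.0, s)),
    "relu": lambda s: float(max(s, 0.0)),
}


@dataclass(frozen=True)
class EstimatorComponent:
    """One estimator component X_i: u_i (dim m) -> x_i (dim n)."""

    id: str
    m: int
    n: int
    kind: str  # "linear_monotone" | "blackbox"
    A: np.ndarray
    b: np.ndarray
    nonlinearity: str = "softplus_floor"
    drift_timescale: float = 100.0
    drift_sd: float = 0.0
    cond_cap: float = 1e4
    A_ref: np.ndarray | None = None  # drift mean-reversion anchors
    b_ref: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear_monotone", "blackbox"):
            raise ValueError(f"unknown component kind {self.kind!r}")
        if self.nonlinearity not in NONLINEARITIES:
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")
        if self.A.shape != (self.n, self.m) or self.b.shape != (self.n,):
            raise ValueError("parameter shapes inconsistent with (n, m)")
        if self.A_ref is None:
            object.__setattr__(self, "A_ref", self.A.copy())
        if self.b_ref is None:
            object.__setattr__(self, "b_ref", self.b.copy())

    def snapshot_hash(self) -> int:
        """Hash of the current parameters; identifies a frozen instance."""
        return hash((self.A.tobytes(), self.b.tobytes(), self.nonlinearity))


@dataclass(frozen=True)
class EstimatorBank:
    """A set of components plus the rule combining them into scalar x."""

    components: tuple[EstimatorComponent, ...]
    weights: np.ndarray | None = None
    output_map: str = "softplus"

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("bank needs at least one component")
        if self.output_map not in OUTPUT_MAPS:
            raise ValueError(f"unknown output_map {self.output_map!r}")
        if self.weights is None:
            object.__setattr__(self, "weights", np.ones(len(self.components)))
        if len(self.weights) != len(self.components):
            raise ValueError("one weight per component required")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")


def clip_condition(A: np.ndarray, cond_cap: float) -> np.ndarray:
    """Clamp singular values so cond(A) <= cond_cap (square matrices)."""
    if A.shape[0] != A.shape[1]:
        return A
    U, s, Vt = np.linalg.svd(A)
    floor = s.max() / cond_cap
    return (U * np.maximum(s, floor)) @ Vt


def make_component(spec: Mapping, seed: int) -> EstimatorComponent:
    """Build a component from a spec record, deterministically per seed.

    Spec keys: ``id, m, n, kind, ensemble ("gaussian"|"identity"),
    nonlinearity, scale, drift_timescale, drift_sd, cond_cap``.  Gaussian
    matrices are resampled (up to 50 draws) until cond(A) <= cond_cap,
    then spectrally clipped as a last resort; a still-violating matrix is
    a construction error.
    """
    m = int(spec["m"])
    n = int(spec["n"])
    if m < 1 or n < 1:
        raise ValueError("component dims must be positive")
    cond_cap = float(spec.get("cond_cap", 1e4))
    ensemble = spec.get("ensemble", "gaussian")
    scale = float(spec.get("scale", 1.0))
    rng = np.random.default_rng(seed)

    if ensemble == "identity":
        if n != m:
            raise ValueError("identity ensemble requires n == m")
        A = np.eye(n)
        b = np.zeros(n)
    elif ensemble == "gaussian":
        A = None
        for _ in range(50):
            cand = scale * rng.standard_normal((n, m)) / np.sqrt(m)
            if n != m or np.linalg.cond(cand) <= cond_cap:
                A = cand
                break
        if A is None:
            cand = clip_condition(cand, cond_cap)
            if np.linalg.cond(cand) > cond_cap * (1 + 1e-9):
                raise RuntimeError("could not satisfy cond_cap after resampling")
            A = cand
        b = 0.1 * scale * rng.standard_normal(n)
    else:
        raise ValueError(f"unknown ensemble {ensemble!r}")

    return EstimatorComponent(
        id=str(spec.get("id", "comp")),
        m=m,
        n=n,
        kind=spec.get("kind", "linear_monotone"),
        A=A,
        b=b,
        nonlinearity=spec.get("nonlinearity", "softplus_floor"),
        drift_timescale=float(spec.get("drift_timescale", 100.0)),
        drift_sd=float(spec.get("drift_sd", 0.0)),
        cond_cap=cond_cap,
    )


def apply_component(comp: EstimatorComponent, u_i: np.ndarray) -> np.ndarray:
    """Forward evaluation x_i = phi(A u_i + b)."""
    u_i = np.asarray(u_i, dtype=float)
    if u_i.shape != (comp.m,):
        raise ValueError(f"input dim {u_i.shape} != ({comp.m},)")
    phi = NONLINEARITIES[comp.nonlinearity][0]
    return np.asarray(phi(comp.A @ u_i + comp.b), dtype=float)


def aggregate_estimate(bank: EstimatorBank, component_outputs: list) -> float:
    """Pool component outputs into the scalar estimate x >= 0.

    x = output_map( sum_i w_i * mean(x_i) ).  The squashing keeps the
    estimate non-negative; with ``relu`` and positive pre-squash sum the
    map is the identity (pass-through regime).
    """
    if len(component_outputs) != len(bank.components):
        raise ValueError("one output per component required")
    s = float(
        sum(w * float(np.mean(x)) for w, x in zip(bank.weights, component_outputs))
    )
    return OUTPUT_MAPS[bank.output_map](s)


def drift_parameters(
    comp: EstimatorComponent, dt: float, rng: np.random.Generator
) -> EstimatorComponent:
    """One slow drift step of the component parameters.

    Each entry of A and b mean-reverts toward its construction value with
    the component's timescale and stationary sd ``drift_sd``; the
    condition cap is re-enforced by spectral clipping.  drift_sd = 0 is a
    no-op.
    """
    if comp.drift_sd == 0.0:
        return comp
    if comp.drift_timescale < 10.0 * dt:
        warnings.warn(
            "drift_timescale is not large relative to dt; the operator will "
            "not be locally stationary",
            stacklevel=2,
        )
    a = min(dt / comp.drift_timescale, 1.0)
    amp = comp.drift_sd * np.sqrt(2.0 * a)
    A = comp.A_ref + (comp.A - comp.A_ref) * (1.0 - a) + amp * rng.standard_normal(
        comp.A.shape
    )
    b = comp.b_ref + (comp.b - comp.b_ref) * (1.0 - a) + amp * rng.standard_normal(
        comp.b.shape
    )
    A = clip_condition(A, comp.cond_cap)
    return replace(comp, A=A, b=b)
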