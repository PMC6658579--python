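"""Approximate operator inversion by a high-gain feedback loop.

The circuit: an amplifier with gain g drives its output q from the
difference between the target p and the fed-back forward image S q, so at
equilibrium q = g·B·(p − S q).  For large gain the residual p − S q is
forced toward zero and q approaches S⁻¹p — inversion without ever
representing an inverse analytically, using only forward evaluations of S.

Two realizations are provided:

* ``invert_fixed_point`` — damped iteration to the loop's equilibrium
  within a single time step; the idealized algorithm.
* ``invert_dynamical`` — explicit relaxation dynamics with an optional
  transmission delay in the feedback path; exposes the stability limits
  of the physical loop (high gain plus delay destabilizes it).

For the linear scalar case S: q ↦ s·q the equilibrium is exactly
q = g·p / (1 + g·s), so the deviation from the true inverse p/s is
p / (s(1 + g·s)) — shrinking as 1/g.  ``analytic_linear_oracle`` computes
the exact inverse of the structured component family and exists for
testing only; nothing in the simulator's loops calls it.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimator import NONLINEARITIES, EstimatorComponent, apply_component

__all__ = [
    "GenericOperator",
    "InversionConfig",
    "InversionResult",
    "operator_from_component",
    "invert",
    "invert_fixed_point",
    "invert_dynamical",
    "analytic_linear_oracle",
    "stability_map",
]

_DIVERGE_NORM_FACTOR = 1e6
_DIVERGE_RESIDUAL_STREAK = 50


@dataclass(frozen=True)
class GenericOperator:
    """A forward-evaluable map; the only interface inversion may use."""

    forward: object  # callable: (m_in,) -> (m_out,)
    m_in: int
    m_out: int

    def __call__(self, q: np.ndarray) -> np.ndarray:
        out = np.asarray(self.forward(q), dtype=float)
        if out.shape != (self.m_out,):
            raise ValueError("operator output has wrong dimension")
        return out


def operator_from_component(comp: EstimatorComponent) -> GenericOperator:
    """View an estimator component as a generic forward operator."""
    return GenericOperator(
        forward=lambda q: apply_component(comp, q), m_in=comp.m, m_out=comp.n
    )


@dataclass(frozen=True)
class InversionConfig:
    """Settings of the feedback-inversion loop.

    gain is the scalar amplifier gain g; the effective gain operator is
    g·B with B either the identity or the transpose of a finite-difference
    linearization of S at q = 0 (normalized by its largest squared
    singular value — a gradient-like preconditioner for non-square or
    ill-conditioned operators).
    """

    gain: float = 100.0
    preconditioner: str = "auto"  # "identity" | "transpose_linearization"
    mode: str = "fixed_point"  # or "dynamical"
    damping: float = 0.5
    tol: float = 1e-10
    max_iter: int = 10_000
    delay_steps: int = 0
    relax_step: float = 0.002
    fd_step: float = 1e-6  # finite-difference step for the linearization

    def __post_init__(self) -> None:
        if not (0 < self.damping <= 1):
            raise ValueError("damping must lie in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.delay_steps < 0:
            raise ValueError("delay_steps must be non-negative")


@dataclass
class InversionResult:
    """Outcome of one inversion: the approximate preimage and diagnostics."""

    q: np.ndarray
    residual: float
    iterations: int
    converged: bool
    diverged: bool
    non_unique: bool = False
    trajectory: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.diverged and self.converged:
            raise ValueError("diverged implies not converged")


def _preconditioner_matrix(
    S: GenericOperator, cfg: InversionConfig
) -> np.ndarray | None:
    kind = cfg.preconditioner
    if kind == "auto":
        # Raw negative feedback through S is only stable when the
        # linearization of S has spectrum in the right half-plane — true
        # for scalar monotone maps, not for generic matrices.  The
        # gradient-like transpose preconditioner makes g·B·S' positive
        # semidefinite and hence stabilizable at any gain.
        kind = "identity" if S.m_in == 1 and S.m_out == 1 else "transpose_linearization"
    if kind == "identity":
        if S.m_in != S.m_out:
            raise ValueError(
                "identity preconditioner requires a square operator; use "
                "preconditioner='transpose_linearization'"
            )
        return None
    if kind == "transpose_linearization":
        q0 = np.zeros(S.m_in)
        f0 = S(q0)
        J = np.empty((S.m_out, S.m_in))
        for j in range(S.m_in):
            dq = q0.copy()
            dq[j] += cfg.fd_step
            J[:, j] = (S(dq) - f0) / cfg.fd_step
        smax = np.linalg.norm(J, 2)
        return J.T / max(smax**2, 1e-12)
    raise ValueError(f"unknown preconditioner {kind!r}")


def _apply_B(B: np.ndarray | None, v: np.ndarray) -> np.ndarray:
    return v if B is None else B @ v


def _loop_gain_estimate(
    S: GenericOperator, B: np.ndarray | None, g: float, fd_step: float
) -> float:
    """Spectral norm of the linearization of q ↦ g·B·S(q) at q = 0.

    Used only to normalize the iteration step; does not change the fixed
    point.
    """
    q0 = np.zeros(S.m_in)
    f0 = _apply_B(B, S(q0))
    J = np.empty((len(f0), S.m_in))
    for j in range(S.m_in):
        dq = q0.copy()
        dq[j] += fd_step
        J[:, j] = (_apply_B(B, S(dq)) - f0) / fd_step
    return g * float(np.linalg.norm(J, 2))


def invert_fixed_point(
    S: GenericOperator, p: np.ndarray, cfg: InversionConfig
) -> InversionResult:
    """Iterate the loop equation to its equilibrium.

    q ← (1−η) q + η · g·B·(p − S q), starting from q₀ = 0, until the step
    ‖Δq‖ ≤ tol·(1 + ‖q‖) or max_iter.  At the fixed point the loop
    equation q = g·B·(p − S q) holds to tolerance.

    The raw iteration contracts only when η(1 + g·‖S'‖) < 2, so at high
    gain the nominal damping is rescaled by the estimated loop gain:
    η_eff = min(η, 2η/(1 + L)) with L = g·‖(B·S)'(0)‖.  This leaves the
    equilibrium untouched and makes ``damping`` a fraction of the
    stability limit.  A residual-growth safeguard halves the step a few
    times before declaring divergence (the local slope of a nonlinear S
    can exceed its slope at 0).
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (S.m_out,):
        raise ValueError("p must have the operator's output dimension")
    B = _preconditioner_matrix(S, cfg)
    g, eta = cfg.gain, cfg.damping
    L = _loop_gain_estimate(S, B, g, cfg.fd_step)
    eta_eff = min(eta, 2.0 * eta / (1.0 + L))
    q = np.zeros(S.m_in)
    converged = diverged = False
    it = 0
    growth_streak = 0
    halvings = 0
    prev_step = np.inf
    for it in range(1, cfg.max_iter + 1):
        target = g * _apply_B(B, p - S(q))
        q_new = (1.0 - eta_eff) * q + eta_eff * target
        if not np.all(np.isfinite(q_new)):
            diverged = True
            break
        step = float(np.linalg.norm(q_new - q))
        if step > prev_step * (1.0 + 1e-12):
            growth_streak += 1
        else:
            growth_streak = 0
        prev_step = step
        q = q_new
        if step <= cfg.tol * (1.0 + float(np.linalg.norm(q))):
            converged = True
            break
        if float(np.linalg.norm(q)) > _DIVERGE_NORM_FACTOR * (
            1.0 + float(np.linalg.norm(p))
        ):
            diverged = True
            break
        if growth_streak >= 20:
            if halvings < 6:
                eta_eff *= 0.5
                halvings += 1
                growth_streak = 0
            else:
                diverged = True
                break
    residual = float(np.linalg.norm(p - S(q))) if np.all(np.isfinite(q)) else np.inf
    return InversionResult(
        q=q,
        residual=residual,
        iterations=it,
        converged=converged and not diverged,
        diverged=diverged,
        non_unique=S.m_out < S.m_in,
    )


def invert_dynamical(
    S: GenericOperator,
    p: np.ndarray,
    cfg: InversionConfig,
    record_trajectory: bool = False,
) -> InversionResult:
    """Integrate the relaxation dynamics of the loop with feedback delay.

    q(t+1) = q(t) + relax_step · (−q(t) + g·B·(p − S q(t − delay)))

    The delayed forward image models slow processing in the feedback
    path.  Divergence is flagged when the iterate norm explodes or the
    residual grows for a sustained streak of steps.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (S.m_out,):
        raise ValueError("p must have the operator's output dimension")
    B = _preconditioner_matrix(S, cfg)
    g = cfg.gain
    q = np.zeros(S.m_in)
    history: deque = deque([q.copy()] * (cfg.delay_steps + 1), maxlen=cfg.delay_steps + 1)
    traj: list = []
    prev_residual = np.inf
    growth_streak = 0
    converged = diverged = False
    it = 0
    last_finite = q.copy()
    for it in range(1, cfg.max_iter + 1):
        q_delayed = history[0]
        drive = g * _apply_B(B, p - S(q_delayed))
        q_new = q + cfg.relax_step * (-q + drive)
        if not np.all(np.isfinite(q_new)):
            diverged = True
            break
        last_finite = q_new
        history.append(q_new.copy())
        step = float(np.linalg.norm(q_new - q))
        q = q_new
        if record_trajectory:
            traj.append(q.copy())
        residual = float(np.linalg.norm(p - S(q)))
        if residual > prev_residual * (1.0 + 1e-12):
            growth_streak += 1
        else:
            growth_streak = 0
        prev_residual = residual
        if float(np.linalg.norm(q)) > _DIVERGE_NORM_FACTOR * (
            1.0 + float(np.linalg.norm(p))
        ):
            diverged = True
            break
        if growth_streak >= _DIVERGE_RESIDUAL_STREAK:
            diverged = True
            break
        if step <= cfg.tol * (1.0 + float(np.linalg.norm(q))):
            converged = True
            break
    q_out = last_finite
    residual = float(np.linalg.norm(p - S(q_out)))
    return InversionResult(
        q=q_out,
        residual=residual,
        iterations=it,
        converged=converged and not diverged,
        diverged=diverged,
        non_unique=S.m_out < S.m_in,
        trajectory=traj,
    )


def invert(
    S: GenericOperator, p: np.ndarray, cfg: InversionConfig
) -> InversionResult:
    """Dispatch on cfg.mode."""
    if cfg.mode == "fixed_point":
        return invert_fixed_point(S, p, cfg)
    if cfg.mode == "dynamical":
        return invert_dynamical(S, p, cfg)
    raise ValueError(f"unknown inversion mode {cfg.mode!r}")


def analytic_linear_oracle(
    A: np.ndarray, b: np.ndarray, phi: str, p: np.ndarray
) -> np.ndarray:
    """Exact inverse of the structured family: A⁻¹(phi⁻¹(p) − b).

    Test oracle only — the simulator never calls this inside its loops.
    """
    A = np.asarray(A, dtype=float)
    if A.shape[0] != A.shape[1]:
        raise ValueError("oracle requires a square A")
    if np.linalg.cond(A) > 1e12:
        raise np.linalg.LinAlgError("A is numerically singular")
    phi_inv = NONLINEARITIES[phi][1]
    z = np.asarray(phi_inv(np.asarray(p, dtype=float)), dtype=float)
    return np.linalg.solve(A, z - np.asarray(b, dtype=float))


def stability_map(
    S: GenericOperator,
    gains: list,
    delays: list,
    cfg: InversionConfig,
    p: np.ndarray | None = None,
) -> pd.DataFrame:
    """Run the dynamical loop over a gain × delay grid on a fixed probe.

    Returns a tidy table (gain, delay, diverged, converged, settle_steps,
    residual) plus a ``monotone_violation`` flag: for each gain, once the
    loop diverges at some delay it should stay divergent at every larger
    tested delay.
    """
    if not gains or not delays:
        raise ValueError("gains and delays grids must be non-empty")
    if p is None:
        p = np.ones(S.m_out)
    rows = []
    for g in gains:
        diverged_seen = False
        for d in sorted(delays):
            from dataclasses import replace as _replace

            res = invert_dynamical(
                S, p, _replace(cfg, gain=float(g), delay_steps=int(d), mode="dynamical")
            )
            violation = diverged_seen and not res.diverged
            diverged_seen = diverged_seen or res.diverged
            rows.append(
                {
                    "gain": float(g),
                    "delay": int(d),
                    "diverged": bool(res.diverged),
                    "converged": bool(res.converged),
                    "settle_steps": int(res.iterations),
                    "residual": float(res.residual),
                    "monotone_violation": bool(violation),
                }
            )
    return pd.DataFrame(rows)
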