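"""Quality metrics for estimation and inversion.

Both metrics follow the same pattern: an error defined as the expected
norm of a difference, and a quality defined as the reciprocal of that
error.  The expectation is realized as a finite-window time average; the
norm is selectable (L2 default for vectors, absolute value for scalars,
L1 offered).  A documented floor of 1e-12 on the error keeps the
reciprocal finite for perfect estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimator import EstimatorComponent, apply_component

__all__ = [
    "EPS_FLOOR",
    "QualityReport",
    "estimation_quality",
    "inversion_quality",
]

EPS_FLOOR = 1e-12


@dataclass(frozen=True)
class QualityReport:
    """Estimation and inversion errors with their reciprocal qualities."""

    eps_X: float
    Q_X: float
    eps_inv: float
    Q_inv: float
    norm: str = "L2"
    window: int = 1


def _norms(diff: np.ndarray, norm: str) -> np.ndarray:
    diff = np.atleast_2d(np.asarray(diff, dtype=float))
    if norm == "L2":
        return np.linalg.norm(diff, axis=-1)
    if norm == "L1":
        return np.sum(np.abs(diff), axis=-1)
    raise ValueError(f"unknown norm {norm!r}")


def estimation_quality(
    x_series, f_series, norm: str = "L1", window: int | None = None
) -> tuple[float, float]:
    """Windowed estimation error eps_X = <|x - f|> and quality 1/eps_X.

    x_series and f_series are aligned scalar time series; the last
    ``window`` samples (default: all) are averaged as the expectation.
    """
    x = np.asarray(x_series, dtype=float)
    f = np.asarray(f_series, dtype=float)
    if x.size == 0 or f.size == 0:
        raise ValueError("series must be non-empty")
    if x.shape != f.shape:
        raise ValueError("series must have equal length")
    if window is None:
        window = x.size
    if window > x.size:
        raise ValueError("window exceeds series length")
    diff = (x - f)[-window:]
    per_sample = _norms(diff[:, None], norm)
    eps = float(np.mean(per_sample))
    return eps, 1.0 / max(eps, EPS_FLOOR)


def inversion_quality(
    x_i: np.ndarray,
    comp: EstimatorComponent,
    u_hat: np.ndarray,
    norm: str = "L2",
) -> tuple[float, float]:
    """Single-shot inversion error eps = ||x_i - X_i(û_i)|| and 1/eps.

    A perfect inversion maps û back onto x_i exactly, so the error is the
    round-trip discrepancy through the forward operator.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_rt = apply_component(comp, np.asarray(u_hat, dtype=float))
    if x_rt.shape != x_i.shape:
        raise ValueError("x_i dimension inconsistent with component output")
    eps = float(_norms((x_i - x_rt)[None, :], norm)[0])
    return eps, 1.0 / max(eps, EPS_FLOOR)
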