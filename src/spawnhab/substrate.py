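"""Threshold (incipient-motion) velocity and its inversion to grain size.

The critical depth-averaged velocity at which a bed particle of diameter
``d`` (m) starts to move under water depth ``h`` (m) is

    U_e = (h/d)^0.14 * [ 17.6 * (rho_s - rho)/rho * d
                         + 0.000000605 * (10 + h) / d^0.72 ]^0.5

with sediment density rho_s = 2.65 g/cm3 and water density rho = 1 g/cm3
(densities enter only through the ratio, so no unit conversion is needed).
The gravity term grows with ``d`` and the cohesion term decays, so U_e is
U-shaped in ``d``; the bed-material estimate inverts the coarse (rising)
branch: given a local velocity, the returned diameter is the finest grain
the flow cannot move, i.e. the winnowed bed-surface size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SedimentParams",
    "GrainEstimate",
    "critical_velocity",
    "ue_minimum",
    "invert_grain_size",
    "invert_grain_size_field",
]

log = logging.getLogger(__name__)

#: Search bracket for grain diameter (m).
D_MIN_BRACKET = 1e-6
D_MAX_BRACKET = 2.0


@dataclass(frozen=True)
class SedimentParams:
    """Densities (g/cm3) and the cohesion coefficient of the U_e formula."""

    rho_s: float = 2.65
    rho: float = 1.0
    cohesion: float = 6.05e-7

    def __post_init__(self) -> None:
        if not self.rho_s > self.rho > 0:
            raise ValueError("require rho_s > rho > 0")

    @property
    def density_ratio(self) -> float:
        return (self.rho_s - self.rho) / self.rho


@dataclass(frozen=True)
class GrainEstimate:
    """Inverted grain diameter with clamping information."""

    d: float
    clamped: bool
    note: str = "coarse branch"


def critical_velocity(h, d, params: SedimentParams = SedimentParams()):
    """Critical (threshold) velocity U_e in m/s for depth ``h`` and grain ``d``."""
    h = np.asarray(h, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(h <= 0) or np.any(d <= 0):
        raise ValueError("depth and grain diameter must be positive")
    inner = 17.6 * params.density_ratio * d + params.cohesion * (10.0 + h) / d**0.72
    out = (h / d) ** 0.14 * np.sqrt(inner)
    return out if out.ndim else float(out)


def ue_minimum(h, params: SedimentParams = SedimentParams(), rel_tol: float = 1e-8):
    """Locate the grain diameter minimizing U_e at depth ``h``.

    Golden-section search on log-diameter over [1e-6, 2] m; vectorized over
    ``h``.  Returns ``(d_min_arg, ue_min)``.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0):
        raise ValueError("depth must be positive")
    scalar = h.ndim == 0
    h = np.atleast_1d(h)

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a = np.full(h.shape, np.log(D_MIN_BRACKET))
    b = np.full(h.shape, np.log(D_MAX_BRACKET))
    c = b - invphi * (b - a)
    dd = a + invphi * (b - a)
    fc = critical_velocity(h, np.exp(c), params)
    fd = critical_velocity(h, np.exp(dd), params)
    # iterations to shrink the log bracket below the relative tolerance
    n_iter = int(np.ceil(np.log(rel_tol / (b[0] - a[0])) / np.log(invphi)))
    for _ in range(n_iter):
        take_left = fc < fd
        b = np.where(take_left, dd, b)
        a = np.where(take_left, a, c)
        c = b - invphi * (b - a)
        dd = a + invphi * (b - a)
        fc = critical_velocity(h, np.exp(c), params)
        fd = critical_velocity(h, np.exp(dd), params)
    d_arg = np.exp(0.5 * (a + b))
    ue = critical_velocity(h, d_arg, params)
    if scalar:
        return float(d_arg[0]), float(ue[0])
    return d_arg, ue


def invert_grain_size_field(
    U, h, params: SedimentParams = SedimentParams(), rel_tol: float = 1e-6
):
    """Vectorized coarse-branch inversion of U_e(h, d) = U.

    Returns ``(d, clamped)`` arrays.  Velocities below the attainable
    minimum clamp to the branch point; velocities above U_e(h, 2 m) clamp
    to the 2 m bracket.
    """
    U = np.atleast_1d(np.asarray(U, dtype=float))
    h = np.broadcast_to(np.asarray(h, dtype=float), U.shape).copy()
    if np.any(~np.isfinite(U)) or np.any(~np.isfinite(h)):
        raise ValueError("non-finite velocity or depth")
    if np.any(U < 0) or np.any(h <= 0):
        raise ValueError("require U >= 0 and h > 0")

    d_lo, ue_lo = ue_minimum(h, params)
    d_lo = np.atleast_1d(d_lo)
    ue_lo = np.atleast_1d(ue_lo)
    ue_hi = critical_velocity(h, np.full(h.shape, D_MAX_BRACKET), params)

    d = np.empty(U.shape)
    clamped = np.zeros(U.shape, dtype=bool)
    low = U <= ue_lo
    high = U >= ue_hi
    d[low] = d_lo[low]
    d[high] = D_MAX_BRACKET
    clamped[low | high] = True

    solve = ~(low | high)
    if solve.any():
        a = np.log(d_lo[solve])
        b = np.full(a.shape, np.log(D_MAX_BRACKET))
        hs = h[solve]
        target = U[solve]
        # bisection on log-diameter; the coarse branch is strictly increasing
        n_iter = int(np.ceil(np.log2((b[0] - a.min()) / rel_tol))) + 2
        for _ in range(max(n_iter, 40)):
            mid = 0.5 * (a + b)
            too_high = critical_velocity(hs, np.exp(mid), params) > target
            b = np.where(too_high, mid, b)
            a = np.where(too_high, a, mid)
        d[solve] = np.exp(0.5 * (a + b))
    if clamped.any():
        log.debug("grain inversion: %d of %d cells clamped", int(clamped.sum()), U.size)
    return d, clamped


def invert_grain_size(
    U: float, h: float, params: SedimentParams = SedimentParams()
) -> GrainEstimate:
    """Scalar coarse-branch inversion; see :func:`invert_grain_size_field`."""
    d, clamped = invert_grain_size_field([U], [h], params)
    note = "coarse branch"
    if clamped[0]:
        note += " (clamped)"
    return GrainEstimate(float(d[0]), bool(clamped[0]), note)
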