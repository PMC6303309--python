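"""Deterministic dynamics of the regulated TX device and its variants.

Reduced regulated model (states m1, s1, y1):

    dm1/dt = T·D·H(u1) − (λ/β)·m1·s1 − δ·m1
    ds1/dt = k·Ts·y1   − (λ/β)·m1·s1 − δ·s1
    dy1/dt = R·(1−d)·m1/κ_GFP − γ·y1

The sensor protein p1 is eliminated using p1 = k·y1, which holds when GFP
and ECF32 decay at the same rate γ and the circuit starts from steady-state
gene expression.  The ``full`` variant keeps p1 explicit and relaxes that
assumption; the ``unregulated`` variant removes the sRNA arm entirely; the
``ideal`` variant is the δ = 0 antithetic-integral limit in which the
steady-state output y1 = T·D·H(u1)/(k·Ts) is independent of the
disturbance d.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .params import DeviceParams, _check_d

__all__ = [
    "Variant",
    "CircuitState",
    "rhs_regulated",
    "rhs_unregulated",
    "rhs_full",
    "rhs_silencing",
    "state_dim",
    "steady_state",
    "SteadyStateError",
]

Variant = Literal["regulated", "unregulated", "ideal", "full"]

_VARIANT_DIMS = {"regulated": 3, "ideal": 3, "unregulated": 2, "full": 4}


def state_dim(variant: str) -> int:
    try:
        return _VARIANT_DIMS[variant]
    except KeyError:
        raise ValueError(
            f"unknown model variant {variant!r}; expected one of {sorted(_VARIANT_DIMS)}"
        ) from None


@dataclass(frozen=True)
class CircuitState:
    """Concentrations of one TX device's species.

    m1: mRNA co-transcript; s1: sRNA; y1: output protein (GFP);
    p1: sensor protein (ECF32), present only in the full model — in the
    reduced model the identity p1 = k·y1 holds by assumption.
    """

    m1: float
    s1: float = 0.0
    y1: float = 0.0
    p1: float | None = None

    def __post_init__(self) -> None:
        for name in ("m1", "s1", "y1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.p1 is not None and self.p1 < 0:
            raise ValueError("p1 must be >= 0")

    def to_array(self, variant: str = "regulated") -> np.ndarray:
        dim = state_dim(variant)
        if dim == 2:
            return np.array([self.m1, self.y1])
        if dim == 3:
            return np.array([self.m1, self.s1, self.y1])
        p1 = self.p1 if self.p1 is not None else 0.0
        return np.array([self.m1, self.s1, self.y1, p1])

    @classmethod
    def from_array(cls, x: np.ndarray, variant: str = "regulated") -> "CircuitState":
        x = np.asarray(x, dtype=float)
        dim = state_dim(variant)
        if x.shape != (dim,):
            raise ValueError(f"variant {variant!r} expects a state of length {dim}")
        if dim == 2:
            return cls(m1=x[0], y1=x[1])
        if dim == 3:
            return cls(m1=x[0], s1=x[1], y1=x[2])
        return cls(m1=x[0], s1=x[1], y1=x[2], p1=x[3])


def rhs_regulated(
    x: np.ndarray, p: DeviceParams, d: float, u1: float = 0.0
) -> np.ndarray:
    """Time derivative of (m1, s1, y1) for the reduced regulated device."""
    _check_d(d)
    m1, s1, y1 = x
    H = p.regulation(u1)
    coupled = p.coupled_rate * m1 * s1
    dm1 = p.T * p.D * H - coupled - p.delta * m1
    ds1 = p.actuation(y1) - coupled - p.delta * s1
    dy1 = p.R * (1.0 - d) * m1 / p.kappa_gfp - p.gamma * y1
    return np.array([dm1, ds1, dy1])


def rhs_unregulated(
    x: np.ndarray, p: DeviceParams, d: float, u1: float = 0.0
) -> np.ndarray:
    """Time derivative of (m1, y1) with the sRNA arm removed (s1 ≡ 0)."""
    _check_d(d)
    m1, y1 = x
    H = p.regulation(u1)
    dm1 = p.T * p.D * H - p.delta * m1
    dy1 = p.R * (1.0 - d) * m1 / p.kappa_gfp - p.gamma * y1
    return np.array([dm1, dy1])


def rhs_full(
    x: np.ndarray, p: DeviceParams, d: float, u1: float = 0.0
) -> np.ndarray:
    """Time derivative of (m1, s1, y1, p1) with the sensor protein explicit.

    The sensor is translated k times faster than the output from the same
    transcript and decays at the shared rate γ; with p1(0) = k·y1(0) the
    deviation p1 − k·y1 decays homogeneously and the reduced model is
    recovered exactly.
    """
    _check_d(d)
    m1, s1, y1, p1 = x
    H = p.regulation(u1)
    coupled = p.coupled_rate * m1 * s1
    tl = p.R * (1.0 - d) * m1 / p.kappa_gfp
    dm1 = p.T * p.D * H - coupled - p.delta * m1
    ds1 = p.actuation_from_sensor(p1) - coupled - p.delta * s1
    dy1 = tl - p.gamma * y1
    dp1 = p.k * tl - p.gamma * p1
    return np.array([dm1, ds1, dy1, dp1])


def rhs_silencing(
    x: np.ndarray, p: DeviceParams, induction: float
) -> np.ndarray:
    """Open-loop silencing circuit: sRNA driven by an induced sensor level.

    ``induction`` is the externally induced sensor-protein concentration;
    sRNA is produced at ``Ts * induction`` (Ts is per unit sensor, as in
    the closed loop) but the feedback loop is open: production does not
    depend on y1.  The target mRNA is constitutive and translation is
    undisturbed (d = 0).
    """
    if induction < 0:
        raise ValueError("induction must be >= 0")
    m1, s1, y1 = x
    coupled = p.coupled_rate * m1 * s1
    dm1 = p.T * p.D - coupled - p.delta * m1
    ds1 = p.Ts * induction - coupled - p.delta * s1
    dy1 = p.R * m1 / p.kappa_gfp - p.gamma * y1
    return np.array([dm1, ds1, dy1])


class SteadyStateError(RuntimeError):
    """Raised when no stable nonnegative fixed point can be located."""


def _jacobian(f, x: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    n = len(x)
    J = np.empty((n, n))
    f0 = f(x)
    for j in range(n):
        h = eps * max(1.0, abs(x[j]))
        xp = x.copy()
        xp[j] += h
        J[:, j] = (f(xp) - f0) / h
    return J


def _unregulated_ss(p: DeviceParams, d: float, u1: float) -> CircuitState:
    H = p.regulation(u1)
    m1 = p.T * p.D * H / p.delta
    y1 = p.R * (1.0 - d) * m1 / (p.kappa_gfp * p.gamma)
    return CircuitState(m1=m1, y1=y1)


def _ideal_ss(p: DeviceParams, d: float, u1: float) -> CircuitState:
    # δ = 0 antithetic limit: production balance TDH = A(y1) fixes y1
    # independently of d; m1 then follows from the translation balance and
    # s1 from the coupled-decay balance.
    H = p.regulation(u1)
    prod = p.T * p.D * H
    if p.actuator_saturation is None:
        y1 = prod / (p.k * p.Ts)
    else:
        K = p.actuator_saturation
        amax = p.Ts * K  # supremum of the saturating actuator
        if prod >= amax:
            raise SteadyStateError(
                "no ideal steady state: mRNA production exceeds the "
                "saturating actuator's maximal sRNA production"
            )
        # invert Ts·K·p1/(K+p1) = prod for p1 = k·y1
        p1 = K * prod / (amax - prod)
        y1 = p1 / p.k
    m1 = p.kappa_gfp * p.gamma * y1 / (p.R * (1.0 - d))
    s1 = prod / (p.coupled_rate * m1)
    return CircuitState(m1=m1, s1=s1, y1=y1)


def _regulated_ss(p: DeviceParams, d: float, u1: float) -> CircuitState:
    if p.delta == 0:
        return _ideal_ss(p, d, u1)
    H = p.regulation(u1)
    prod = p.T * p.D * H
    if prod == 0:
        return CircuitState(0.0, 0.0, 0.0)
    c = p.coupled_rate
    a = p.kappa_gfp * p.gamma / (p.R * (1.0 - d))  # m1 = a·y1 at equilibrium

    # At a fixed point, subtracting the sRNA from the mRNA balance gives
    # prod − A(y1) = δ·(m1 − s1), so s1 is known once y1 is.  The remaining
    # mRNA balance f(y1) = 0 changes sign between y1 = 0 (f = prod > 0) and
    # the unregulated output (f < 0), so brentq brackets the root.
    def f(y1: float) -> float:
        m1 = a * y1
        s1 = m1 - (prod - p.actuation(y1)) / p.delta
        return prod - c * m1 * s1 - p.delta * m1

    y_hi = p.R * (1.0 - d) * prod / (p.delta * p.kappa_gfp * p.gamma)
    lo, hi = 0.0, y_hi
    if f(hi) >= 0:  # e.g. Ts == 0: feedback absent, root at the unregulated point
        y1 = y_hi
    else:
        y1 = brentq(f, lo, hi, xtol=1e-14, rtol=1e-13)
    m1 = a * y1
    s1 = max(m1 - (prod - p.actuation(y1)) / p.delta, 0.0)
    return CircuitState(m1=m1, s1=s1, y1=y1)


def steady_state(
    p: DeviceParams,
    d: float = 0.0,
    u1: float = 0.0,
    variant: Variant = "regulated",
    check_stability: bool = True,
) -> CircuitState:
    """Locate the device's steady state for a constant disturbance d.

    ``unregulated`` and ``ideal`` use closed forms; ``regulated`` and
    ``full`` find the fixed point numerically (the full model's fixed point
    coincides with the reduced one, with p1 = k·y1).  When
    ``check_stability`` is set the Jacobian at the fixed point is required
    to have eigenvalues with negative real parts.
    """
    _check_d(d)
    if variant == "unregulated":
        return _unregulated_ss(p, d, u1)
    if variant == "ideal":
        ss = _ideal_ss(p, d, u1)
    elif variant in ("regulated", "full"):
        ss = _regulated_ss(p, d, u1)
    else:
        state_dim(variant)  # raises with the standard message
        raise AssertionError("unreachable")

    if variant == "full":
        ss = CircuitState(m1=ss.m1, s1=ss.s1, y1=ss.y1, p1=p.k * ss.y1)

    if check_stability and ss.y1 > 0:
        rhs = rhs_full if variant == "full" else rhs_regulated
        x = ss.to_array(variant if variant != "ideal" else "regulated")
        J = _jacobian(lambda z: rhs(z, p, d, u1), x)
        eigs = np.linalg.eigvals(J)
        if np.any(eigs.real > 1e-9 * max(1.0, np.abs(eigs.real).max())):
            raise SteadyStateError(
                f"fixed point is unstable (Jacobian eigenvalues {eigs})"
            )
    return ss
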