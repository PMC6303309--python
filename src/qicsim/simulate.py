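"""Time-domain integration of the device models.

Integration uses a stiff solver (BDF) restarted at every disturbance
breakpoint, so the piecewise-constant disturbance is handled exactly rather
than through event detection.  The default experiment mirrors the circuit
characterisation protocol: pre-equilibrate without the competitor, then
apply a step decrease in free-ribosome availability at t = 0 and follow the
output's dip and recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    CircuitState,
    Variant,
    rhs_full,
    rhs_regulated,
    rhs_unregulated,
    state_dim,
    steady_state,
)
from .params import DeviceParams, DisturbanceProfile

__all__ = ["Trajectory", "StepSummary", "simulate", "step_response", "SimulationError"]

_RHS = {"regulated": rhs_regulated, "ideal": rhs_regulated,
        "unregulated": rhs_unregulated, "full": rhs_full}

#: default solver tolerances; tight because steady-state cross-checks
#: compare integration endpoints against root finding
RTOL = 1e-8
ATOL = 1e-10

#: output grid density per disturbance segment
POINTS_PER_SEGMENT = 500

#: tolerance below which small negative solver excursions are clipped to 0
NEGATIVITY_TOL = 1e-9


class SimulationError(RuntimeError):
    """Solver failure; carries the last successfully integrated time."""

    def __init__(self, message: str, t_last: float | None = None):
        super().__init__(message)
        self.t_last = t_last


@dataclass
class Trajectory:
    """Simulated time course of one device.

    ``states`` has one row per time point and columns (m1, y1),
    (m1, s1, y1) or (m1, s1, y1, p1) depending on the variant.
    ``z = m1 − s1`` is the controller's memory variable and
    ``e = T·D·H(u1)/(k·Ts) − y1`` the tracking error against the ideal
    set point (both only meaningful for regulated variants).
    """

    times: np.ndarray
    states: np.ndarray
    d_applied: np.ndarray
    variant: str
    params: DeviceParams
    u1: float = 0.0

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def m1(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def s1(self) -> np.ndarray:
        if self.variant == "unregulated":
            return np.zeros_like(self.times)
        return self.states[:, 1]

    @property
    def y1(self) -> np.ndarray:
        return self.states[:, 1 if self.variant == "unregulated" else 2]

    @property
    def p1(self) -> np.ndarray | None:
        return self.states[:, 3] if self.variant == "full" else None

    @property
    def z(self) -> np.ndarray:
        """Memory variable z = m1 − s1."""
        return self.m1 - self.s1

    @property
    def e(self) -> np.ndarray:
        """Tracking error e = T·D·H(u1)/(k·Ts) − y1 against the ideal set point.

        NaN when the device has no sRNA arm (Ts = 0): the set point is
        undefined without feedback.
        """
        p = self.params
        if p.Ts == 0:
            return np.full_like(self.times, np.nan)
        setpoint = p.T * p.D * p.regulation(self.u1) / (p.k * p.Ts)
        return setpoint - self.y1

    def final_state(self) -> CircuitState:
        arr_variant = "regulated" if self.variant == "ideal" else self.variant
        return CircuitState.from_array(self.states[-1], arr_variant)

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: time, m1, s1, y1, (p1,) d, z, e — fixed column order."""
        cols: dict[str, np.ndarray] = {
            "time": self.times,
            "m1": self.m1,
            "s1": self.s1,
            "y1": self.y1,
        }
        if self.p1 is not None:
            cols["p1"] = self.p1
        cols["d"] = self.d_applied
        cols["z"] = self.z
        cols["e"] = self.e
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _integrate_segment(fun, t0, t1, x0, rtol, atol, grid):
    sol = solve_ivp(fun, (t0, t1), x0, method="BDF", rtol=rtol, atol=atol,
                    dense_output=True)
    if not sol.success:
        raise SimulationError(f"stiff solver failed: {sol.message}", t_last=sol.t[-1])
    xs = sol.sol(grid).T
    if xs.min() < -NEGATIVITY_TOL * max(1.0, np.abs(xs).max()):
        raise SimulationError(
            f"state went negative beyond tolerance (min {xs.min():.3e})",
            t_last=float(grid[np.argmin(xs.min(axis=1))]),
        )
    return np.clip(xs, 0.0, None), sol.y[:, -1]


def simulate(
    params: DeviceParams,
    variant: Variant = "regulated",
    disturbance: DisturbanceProfile | float = 0.0,
    u1: float = 0.0,
    t_span: tuple[float, float] = (0.0, 10.0),
    initial: Union[CircuitState, str] = "equilibrate",
    rtol: float = RTOL,
    atol: float = ATOL,
    points_per_segment: int = POINTS_PER_SEGMENT,
) -> Trajectory:
    """Integrate a model variant over ``t_span`` under a disturbance profile.

    ``initial`` may be a :class:`CircuitState` or the string
    ``"equilibrate"``, which starts from the steady state at the profile's
    initial disturbance value.  The integrator restarts at each disturbance
    breakpoint so that discontinuities in d are exact.
    """
    if variant == "ideal" and params.delta != 0.0:
        # the ideal variant IS the δ = 0 limit; force it so dynamics and
        # closed-form steady states agree
        from dataclasses import replace

        params = replace(params, delta=0.0)
    if isinstance(disturbance, (int, float)):
        disturbance = DisturbanceProfile.constant(float(disturbance))
    t0, t1 = map(float, t_span)
    if not (np.isfinite(t0) and np.isfinite(t1)) or t1 <= t0:
        raise ValueError("t_span must be finite with t_span[1] > t_span[0]")

    arr_variant = "regulated" if variant == "ideal" else variant
    if isinstance(initial, str):
        if initial != "equilibrate":
            raise ValueError("initial must be a CircuitState or 'equilibrate'")
        x0_state = steady_state(params, float(disturbance(t0)), u1, variant)
        x0 = x0_state.to_array(arr_variant)
    else:
        x0 = initial.to_array(arr_variant)
    state_dim(arr_variant)
    rhs = _RHS[variant]

    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    d_out: list[np.ndarray] = []
    x = np.asarray(x0, dtype=float)
    segs = disturbance.segments(t0, t1)
    for i, (a, b, d) in enumerate(segs):
        grid = np.linspace(a, b, points_per_segment)
        fun = lambda t, xx: rhs(xx, params, d, u1)  # noqa: E731
        xs, x = _integrate_segment(fun, a, b, x, rtol, atol, grid)
        # a breakpoint time belongs to the NEXT segment (half-open
        # intervals), so drop each non-final segment's endpoint: the state
        # there is continuous and reappears as the next segment's start
        sl = slice(None) if i == len(segs) - 1 else slice(None, -1)
        times_out.append(grid[sl])
        states_out.append(xs[sl])
        d_out.append(np.full(len(grid), d)[sl])

    return Trajectory(
        times=np.concatenate(times_out),
        states=np.concatenate(states_out),
        d_applied=np.concatenate(d_out),
        variant=variant,
        params=params,
        u1=u1,
    )


@dataclass(frozen=True)
class StepSummary:
    """Summary of a step-disturbance experiment on one device."""

    d_step: float
    pre_step_output: float
    post_step_min: float
    final_output: float
    settling_time: float | None
    settling_threshold: float = 0.02

    @property
    def recovery_ratio(self) -> float:
        """final/pre-step output; 1 means perfect adaptation."""
        return self.final_output / self.pre_step_output


def step_response(
    params: DeviceParams,
    variant: Variant = "regulated",
    d_step: float = 0.5,
    u1: float = 0.0,
    horizon: float = 10.0,
    settling_threshold: float = 0.02,
    **sim_kw,
) -> tuple[Trajectory, StepSummary]:
    """Equilibrate at d = 0, then step the disturbance to ``d_step`` at t = 0.

    Returns the trajectory on [0, horizon] and a summary with the pre-step
    output, the post-step minimum, the final output and the settling time
    (first time after which |y1 − y1(final)| stays below
    ``settling_threshold`` · y1(final)).
    """
    pre = steady_state(params, 0.0, u1, variant)
    traj = simulate(
        params,
        variant,
        DisturbanceProfile.step(d_step, t_step=0.0),
        u1,
        (0.0, horizon),
        initial=pre,
        **sim_kw,
    )
    y = traj.y1
    y_final = float(y[-1])
    settling: float | None = None
    if y_final > 0:
        outside = np.nonzero(np.abs(y - y_final) >= settling_threshold * y_final)[0]
        if len(outside) == 0:
            settling = float(traj.times[0])
        elif outside[-1] + 1 < len(y):
            settling = float(traj.times[outside[-1] + 1])
    summary = StepSummary(
        d_step=d_step,
        pre_step_output=float(pre.y1),
        post_step_min=float(y.min()),
        final_output=y_final,
        settling_time=settling,
        settling_threshold=settling_threshold,
    )
    return traj, summary
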