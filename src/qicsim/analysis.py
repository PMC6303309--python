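"""Controller-performance metrics and design diagnostics.

Robustness is the steady-state output under disturbance as a percentage of
the nominal (undisturbed) output — 100% means a perfectly modular device.
The quasi-integral-control (QIC) check evaluates the three timescale
ratios that must be small for the leaky antithetic integrator to behave
like an ideal one: δ/λ (coupled decay fast), δ/T (mRNA transcription
fast) and δ/(k·Ts) (error amplification fast).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import SteadyStateError, rhs_regulated, steady_state
from .params import DeviceParams, _check_d
from .simulate import Trajectory

__all__ = [
    "RobustnessResult",
    "QicReport",
    "SweepResult",
    "robustness",
    "qic_check",
    "memory_residual",
    "adaptation_error",
    "sweep",
    "competitor_to_disturbance",
    "silencing_dose_response",
]


@dataclass(frozen=True)
class RobustnessResult:
    """Nominal and perturbed steady-state outputs and their ratio in percent."""

    nominal_output: float
    perturbed_output: float
    d_active: float

    @property
    def robustness(self) -> float:
        """perturbed/nominal × 100 (%)."""
        return self.perturbed_output / self.nominal_output * 100.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["robustness_pct"] = self.robustness
        return d


def robustness(
    params: DeviceParams,
    variant: str = "regulated",
    d_active: float = 0.5,
    u1: float = 0.0,
) -> RobustnessResult:
    """Steady-state output at d = d_active as a percentage of the d = 0 output."""
    _check_d(d_active)
    nominal = steady_state(params, 0.0, u1, variant).y1
    if nominal <= 0:
        raise SteadyStateError("robustness undefined: nominal output is zero")
    perturbed = steady_state(params, d_active, u1, variant).y1
    return RobustnessResult(nominal, perturbed, d_active)


@dataclass(frozen=True)
class QicReport:
    """The three quasi-integral design ratios with pass/fail flags.

    A condition passes when its ratio is below the threshold epsilon
    (default 0.1 as an operational reading of "much less than 1"); the raw
    ratios are always carried so stricter cutoffs can be applied.
    """

    r_lambda: float  # δ/λ — coupled decay vs uncoupled decay
    r_T: float       # δ/T — transcription vs decay
    r_gain: float    # δ/(k·Ts) — error amplification vs decay
    epsilon: float = 0.1

    @property
    def flags(self) -> tuple[bool, bool, bool]:
        return (
            self.r_lambda < self.epsilon,
            self.r_T < self.epsilon,
            self.r_gain < self.epsilon,
        )

    @property
    def passes(self) -> bool:
        return all(self.flags)

    def to_dict(self) -> dict:
        f = self.flags
        return {
            "r_lambda": self.r_lambda,
            "r_T": self.r_T,
            "r_gain": self.r_gain,
            "epsilon": self.epsilon,
            "pass_coupled_decay": f[0],
            "pass_transcription": f[1],
            "pass_gain": f[2],
            "pass_all": self.passes,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def qic_check(params: DeviceParams, epsilon: float = 0.1) -> QicReport:
    """Evaluate the three quasi-integral conditions for a parameter set."""
    for name in ("lam", "T", "Ts"):
        if getattr(params, name) <= 0:
            raise ValueError(f"{name} must be > 0 for the QIC check")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    return QicReport(
        r_lambda=params.delta / params.lam,
        r_T=params.delta / params.T,
        r_gain=params.delta / (params.k * params.Ts),
        epsilon=epsilon,
    )


def memory_residual(traj: Trajectory, scaled: bool = True) -> float:
    """Worst-case residual of the leaky-memory law dz/dt = k·Ts·e − δ·z.

    The memory variable z = m1 − s1 of the reduced regulated model obeys
    this law exactly (it is the difference of the mRNA and sRNA balances),
    so the residual — computed from RHS values, not finite differences —
    measures implementation consistency only.  Returned relative to
    max |dz/dt| when ``scaled`` (falling back to absolute if dz/dt ≈ 0).
    """
    if traj.variant not in ("regulated", "ideal"):
        raise ValueError(
            f"memory residual is defined for the regulated reduced model, "
            f"got a {traj.variant!r} trajectory"
        )
    p = traj.params
    if p.actuator_saturation is not None:
        raise ValueError("memory residual requires the linear actuator")
    from dataclasses import replace

    if traj.variant == "ideal" and p.delta != 0.0:
        p = replace(p, delta=0.0)
    dzdt = np.array(
        [
            (lambda dx: dx[0] - dx[1])(rhs_regulated(x, p, d, traj.u1))
            for x, d in zip(traj.states, traj.d_applied)
        ]
    )
    law = p.k * p.Ts * traj.e - p.delta * traj.z
    resid = float(np.max(np.abs(dzdt - law)))
    if scaled:
        # scale by the magnitude of the law's terms, not max|dz/dt| alone:
        # on an equilibrated trajectory dz/dt ≈ 0 while the opposing terms
        # stay O(production), and that cancellation is the relevant scale
        scale = float(
            np.max(np.abs(p.k * p.Ts * traj.e)) + np.max(np.abs(p.delta * traj.z))
            + np.max(np.abs(dzdt))
        )
        if scale > 0:
            return resid / scale
    return resid


def adaptation_error(
    params: DeviceParams, d: float = 0.0, u1: float = 0.0
) -> float:
    """Relative steady-state deviation of the leaky controller from the
    ideal set point T·D·H(u1)/(k·Ts)."""
    setpoint = params.T * params.D * params.regulation(u1) / (params.k * params.Ts)
    y = steady_state(params, d, u1, "regulated").y1
    return abs(y - setpoint) / setpoint


@dataclass
class SweepResult:
    """Per-point steady states and robustness along one swept axis."""

    axis: str
    values: np.ndarray
    frame: pd.DataFrame

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def sweep(
    params: DeviceParams,
    variant: str = "regulated",
    axis: Literal["gain", "disturbance", "input"] = "disturbance",
    values: Sequence[float] = (),
    d_active: float = 0.5,
    u1: float = 0.0,
) -> SweepResult:
    """Steady state and robustness along a grid of gains, disturbances or inputs.

    Gain sweeps vary kappa_ecf with kappa_gfp held fixed, mirroring tuning
    through the sensor RBS strength.  For the ``disturbance`` axis,
    robustness is reported at each swept d; for the other axes it is
    reported at ``d_active``.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("sweep needs at least one axis value")
    rows = []
    for v in values:
        try:
            if axis == "gain":
                p, dd, uu = params.with_gain(v), d_active, u1
            elif axis == "disturbance":
                p, dd, uu = params, float(v), u1
            elif axis == "input":
                p, dd, uu = params, d_active, float(v)
            else:
                raise ValueError(f"unknown sweep axis {axis!r}")
            ss = steady_state(p, dd if axis == "disturbance" else 0.0, uu, variant)
            rob = robustness(p, variant, dd, uu).robustness if dd > 0 else 100.0
        except (SteadyStateError, ValueError) as err:
            raise type(err)(f"sweep failed at {axis}={v}: {err}") from err
        rows.append(
            {"axis_value": v, "m1": ss.m1, "s1": ss.s1, "y1": ss.y1,
             "robustness_pct": rob}
        )
    return SweepResult(axis=axis, values=values, frame=pd.DataFrame(rows))


def competitor_to_disturbance(
    inducer_level: float, d_max: float, K_half: float, hill_n: float = 1.0
) -> float:
    """Map a competitor inducer level (e.g. AHL) onto the disturbance d.

    Hill form d = d_max · L^n / (K_half^n + L^n): zero without inducer,
    half-maximal at K_half, saturating at d_max < 1.  This is a modelling
    convenience — the circuit model treats d as exogenous.
    """
    if not (0.0 <= d_max < 1.0):
        raise ValueError("d_max must satisfy 0 <= d_max < 1")
    if K_half <= 0 or hill_n <= 0:
        raise ValueError("K_half and hill_n must be > 0")
    if inducer_level < 0:
        raise ValueError("inducer_level must be >= 0")
    Ln = inducer_level ** hill_n
    return d_max * Ln / (K_half ** hill_n + Ln)


def _silencing_ss(p: DeviceParams, induction: float) -> tuple[float, float, float]:
    # Open-loop steady state: subtracting the RNA balances gives
    # Ts·f − TD = δ(s − m), so m alone parametrises the fixed point.
    prod_m = p.T * p.D
    prod_s = p.Ts * induction
    c = p.coupled_rate
    if p.delta == 0:
        raise SteadyStateError("open-loop silencing requires delta > 0")

    def f(m: float) -> float:
        s = m + (prod_s - prod_m) / p.delta
        return prod_m - c * m * s - p.delta * m

    m_hi = prod_m / p.delta
    if f(m_hi) >= 0:
        m = m_hi
    else:
        m = brentq(f, 0.0, m_hi, xtol=1e-14, rtol=1e-13)
    s = max(m + (prod_s - prod_m) / p.delta, 0.0)
    y = p.R * m / (p.kappa_gfp * p.gamma)
    return m, s, y


def silencing_dose_response(
    inducer_grid: Sequence[float],
    params: DeviceParams,
    K_half: float = 30.0,
    hill_n: float = 2.0,
    basal: float = 0.0,
    sensor_max: float = 300.0,
) -> pd.DataFrame:
    """Steady-state output of the open-loop silencing circuit per inducer dose.

    The sensor is induced externally instead of being fed back from the
    output, emulating the characterisation circuit in which inducer-driven
    sensor expression transcribes the silencing sRNA against a
    constitutively transcribed target.  The induced sensor level is
    ``sensor_max · (basal + (1 − basal) · Hill(dose))`` with Hill constants
    ``K_half`` and ``hill_n``; ``sensor_max`` (conc) is the fully-induced
    sensor concentration.  Output is monotone non-increasing in the dose.
    """
    if not (0.0 <= basal <= 1.0):
        raise ValueError("basal leak must be in [0, 1]")
    if sensor_max <= 0:
        raise ValueError("sensor_max must be > 0")
    rows = []
    for dose in inducer_grid:
        if dose < 0:
            raise ValueError("inducer doses must be >= 0")
        dn = dose ** hill_n
        f = sensor_max * (basal + (1.0 - basal) * dn / (K_half ** hill_n + dn))
        m, s, y = _silencing_ss(params, f)
        rows.append({"inducer": dose, "induction": f, "m1": m, "s1": s, "y1": y})
    return pd.DataFrame(rows)
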