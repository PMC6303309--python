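"""Parameter and input types for the sRNA-feedback transcriptional device model.

A transcriptional (TX) device produces an mRNA co-transcript ``m1`` carrying
both the output protein (GFP) and an ECF sigma-factor sensor.  The sensor
actuates transcription of a small RNA that silences ``m1`` by coupled
degradation, closing a negative feedback loop.  Competing gene expression is
summarised by a single exogenous disturbance ``d`` — the fold change in free
ribosome availability, ``0 <= d < 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Regulation",
    "constitutive",
    "hill_activation",
    "hill_repression",
    "feedback_gain",
    "feedback_gain_from_tir",
    "DeviceParams",
    "DisturbanceProfile",
]


@dataclass(frozen=True)
class Regulation:
    """Transcriptional regulation H(u1) of the device promoter, valued in [0, 1].

    ``kind`` is one of ``"constitutive"`` (H == 1), ``"activation"``
    (Hill activation ``u^n / (K^n + u^n)``) or ``"repression"``
    (``K^n / (K^n + u^n)``).
    """

    kind: str = "constitutive"
    K: float = 1.0
    n: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("constitutive", "activation", "repression"):
            raise ValueError(f"unknown regulation kind {self.kind!r}")
        if self.kind != "constitutive":
            if self.K <= 0:
                raise ValueError("Hill constant K must be > 0")
            if self.n <= 0:
                raise ValueError("Hill coefficient n must be > 0")

    def __call__(self, u1: float) -> float:
        if u1 < 0:
            raise ValueError("regulatory input u1 must be >= 0")
        if self.kind == "constitutive":
            return 1.0
        un = u1 ** self.n
        Kn = self.K ** self.n
        if self.kind == "activation":
            return un / (Kn + un)
        return Kn / (Kn + un)


def constitutive() -> Regulation:
    """H(u1) == 1: a constitutive promoter, as in the test-bed devices."""
    return Regulation("constitutive")


def hill_activation(K: float, n: float = 1.0) -> Regulation:
    return Regulation("activation", K=K, n=n)


def hill_repression(K: float, n: float = 1.0) -> Regulation:
    return Regulation("repression", K=K, n=n)


def feedback_gain(kappa_gfp: float, kappa_ecf: float) -> float:
    """Feedback gain k = kappa_GFP / kappa_ECF32.

    The gain is the ratio of the output-protein RBS dissociation constant to
    the sensor-protein RBS dissociation constant; because both proteins are
    translated from the same co-transcript, the sensor translation rate is
    ``k`` times the output translation rate.

    Raises ``ValueError`` for nonpositive dissociation constants.
    """
    if kappa_gfp <= 0 or kappa_ecf <= 0:
        raise ValueError("RBS dissociation constants must be > 0")
    return kappa_gfp / kappa_ecf


def feedback_gain_from_tir(tir_gfp: float, tir_ecf: float) -> float:
    """Feedback gain from RBS-calculator translation initiation rates.

    Convention: TIR is inversely proportional to the RBS dissociation
    constant kappa (unit proportionality), so k = TIR_ECF / TIR_GFP.
    """
    if tir_gfp <= 0 or tir_ecf <= 0:
        raise ValueError("TIR values must be > 0")
    return tir_ecf / tir_gfp


@dataclass(frozen=True)
class DeviceParams:
    """All rate constants of one TX device and its sRNA controller.

    Units are hours for time and nM-like arbitrary concentration units.

    Parameters
    ----------
    T : transcription rate constant per DNA copy of the device mRNA
        (conc · h⁻¹ · copy⁻¹).
    D : plasmid copy number of the regulated gene.
    kappa_gfp, kappa_ecf : RBS dissociation constants of the output (GFP)
        and sensor (ECF32) proteins (conc).  The feedback gain is their
        ratio ``k = kappa_gfp / kappa_ecf``.
    Ts : lumped sRNA transcription rate constant (h⁻¹ per unit sensor
        protein concentration).
    delta : uncoupled mRNA/sRNA decay rate constant δ (h⁻¹); assumed equal
        for both RNA species.
    lam, beta : mRNA–sRNA coupled decay rate constant λ (h⁻¹) and binding
        dissociation constant β (conc).  They enter the dynamics only as
        the effective second-order rate λ/β.
    R : maximum translation rate constant, proportional to total ribosomes
        (conc · h⁻¹).
    gamma : protein decay/dilution rate constant γ (h⁻¹).
    regulation : promoter regulation H(u1); defaults to constitutive.
    actuator_saturation : optional half-saturation constant (conc) for
        sRNA transcription in the sensor protein.  ``None`` gives the
        linear actuator ``k·Ts·y1``; a finite value K gives
        ``Ts·K·(k·y1)/(K + k·y1)``, which recovers the linear law as
        K → ∞.
    """

    T: float
    D: float
    kappa_gfp: float
    kappa_ecf: float
    Ts: float
    delta: float
    lam: float
    beta: float
    R: float
    gamma: float
    regulation: Regulation = field(default_factory=constitutive)
    actuator_saturation: float | None = None

    def __post_init__(self) -> None:
        for name in ("T", "Ts", "delta", "lam", "R", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.D < 1:
            raise ValueError("plasmid copy number D must be >= 1")
        if self.kappa_gfp <= 0 or self.kappa_ecf <= 0:
            raise ValueError("RBS dissociation constants must be > 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.actuator_saturation is not None and self.actuator_saturation <= 0:
            raise ValueError("actuator_saturation must be > 0 when given")

    @property
    def k(self) -> float:
        """Feedback gain k = kappa_gfp / kappa_ecf."""
        return feedback_gain(self.kappa_gfp, self.kappa_ecf)

    @property
    def coupled_rate(self) -> float:
        """Effective second-order mRNA–sRNA removal rate λ/β (conc⁻¹ h⁻¹)."""
        return self.lam / self.beta

    def with_gain(self, k: float) -> "DeviceParams":
        """Return a copy with feedback gain ``k``, varying kappa_ecf only.

        Mirrors the experimental tuning knob: the gain is set through the
        sensor RBS strength while the output RBS (kappa_gfp) is unchanged.
        """
        if k <= 0:
            raise ValueError("feedback gain k must be > 0")
        return replace(self, kappa_ecf=self.kappa_gfp / k)

    def actuation(self, y1: float | np.ndarray) -> float | np.ndarray:
        """sRNA production rate as a function of the output protein y1.

        Linear by default (``k·Ts·y1``); Michaelis–Menten-saturating in the
        sensor protein ``p1 = k·y1`` when ``actuator_saturation`` is set.
        """
        p1 = self.k * y1
        if self.actuator_saturation is None:
            return self.Ts * p1
        K = self.actuator_saturation
        return self.Ts * K * p1 / (K + p1)

    def actuation_from_sensor(self, p1: float | np.ndarray) -> float | np.ndarray:
        """sRNA production rate from an explicit sensor-protein level p1."""
        if self.actuator_saturation is None:
            return self.Ts * p1
        K = self.actuator_saturation
        return self.Ts * K * p1 / (K + p1)


def _check_d(d: float) -> float:
    if not (0.0 <= d < 1.0):
        raise ValueError(f"disturbance must satisfy 0 <= d < 1, got {d}")
    return float(d)


@dataclass(frozen=True)
class DisturbanceProfile:
    """Piecewise-constant free-ribosome disturbance d(t).

    ``values[i]`` applies on the half-open interval
    ``[breakpoints[i], breakpoints[i+1])``; ``values[0]`` applies before the
    first breakpoint and ``values[-1]`` after the last one.  There is one
    more value than breakpoints.
    """

    breakpoints: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        bp = tuple(float(t) for t in self.breakpoints)
        vals = tuple(_check_d(v) for v in self.values)
        if len(vals) != len(bp) + 1:
            raise ValueError(
                "need exactly one more disturbance value than breakpoints"
            )
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "values", vals)

    @classmethod
    def constant(cls, d: float) -> "DisturbanceProfile":
        return cls((), (d,))

    @classmethod
    def step(cls, d_after: float, t_step: float = 0.0, d_before: float = 0.0) -> "DisturbanceProfile":
        """A single step from ``d_before`` to ``d_after`` at ``t_step``."""
        return cls((t_step,), (d_before, d_after))

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        idx = np.searchsorted(self.breakpoints, t, side="right")
        out = np.asarray(self.values)[idx]
        return float(out) if np.isscalar(t) else out

    def segments(self, t0: float, t1: float) -> list[tuple[float, float, float]]:
        """Split [t0, t1] at interior breakpoints: (start, end, d) triples."""
        if t1 <= t0:
            raise ValueError("need t1 > t0")
        cuts = [t0] + [b for b in self.breakpoints if t0 < b < t1] + [t1]
        return [(a, b, float(self(a))) for a, b in zip(cuts, cuts[1:])]
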