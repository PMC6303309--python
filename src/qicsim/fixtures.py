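"""Named parameter sets for the circuit library.

Twelve devices: {stronger, weaker promoter} × {low, medium, high feedback
gain} × {regulated, unregulated}.  Gains follow the sensor-RBS translation
initiation rates (TIR) 565, 1127 and 6474 against the fixed output RBS TIR
of 974, under the convention TIR ∝ 1/κ, so k = TIR_sensor/TIR_output.

Rate constants are representative defaults in hours / nM-like units (the
circuits' fitted constants are not published); see docs/methods.md for the
physiological reasoning behind each value.  All are overridable through
``DeviceParams`` replacement or the config layer.
"""

from __future__ import annotations

from dataclasses import replace

from .params import DeviceParams, feedback_gain_from_tir

__all__ = ["TIR_GFP", "TIR_ECF", "GAINS", "fixtures", "fixture_names"]

#: output-RBS translation initiation rate (RBS-calculator units), fixed
TIR_GFP = 974.0
#: sensor-RBS TIRs giving low / medium / high feedback gain
TIR_ECF = {"low": 565.0, "medium": 1127.0, "high": 6474.0}

GAINS = {name: feedback_gain_from_tir(TIR_GFP, tir) for name, tir in TIR_ECF.items()}

#: transcription rate constant per copy (nM/h) for the two promoters
_PROMOTER_T = {"strong": 300.0, "weak": 100.0}

# Shared representative constants (hours, nM):
#   delta = 8 h⁻¹   ~5-min uncoupled RNA half-life (degradation + dilution)
#   gamma = 1.4 h⁻¹  dilution-dominated protein decay (~30-min doubling)
#   lam/beta = 80 nM⁻¹h⁻¹  fast sRNA-mediated coupled decay (condition I)
#   Ts = 20 h⁻¹      modest sRNA promoter activity
_BASE = dict(
    D=10.0,
    kappa_gfp=100.0,
    Ts=20.0,
    delta=8.0,
    lam=800.0,
    beta=10.0,
    R=1000.0,
    gamma=1.4,
)


def _make(promoter: str, gain: str, regulated: bool) -> DeviceParams:
    k = GAINS[gain]
    p = DeviceParams(
        T=_PROMOTER_T[promoter],
        kappa_ecf=_BASE["kappa_gfp"] / k,
        **_BASE,
    )
    if not regulated:
        p = replace(p, Ts=0.0)  # pECF32 promoter and sRNA removed
    return p


_REGISTRY: dict[str, DeviceParams] = {
    f"{prom}-{gain}-{'regulated' if reg else 'unregulated'}": _make(prom, gain, reg)
    for prom in ("strong", "weak")
    for gain in ("low", "medium", "high")
    for reg in (True, False)
}


def fixture_names() -> list[str]:
    return sorted(_REGISTRY)


def fixtures(name: str) -> DeviceParams:
    """Look up a named device parameter set.

    Names follow ``{strong|weak}-{low|medium|high}-{regulated|unregulated}``.
    """
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        ) from None
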