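"""Feedback-gain tuning: robustness across the device library.

The feedback gain k is the ratio of output-RBS to sensor-RBS dissociation
constants and is tuned experimentally through the sensor RBS strength.
Higher gain amplifies the error signal faster than the RNA controller
species decay, so robustness to ribosome competition increases with gain.
"""

from qicsim import fixtures, qic_check, robustness

print(f"{'device':28s} {'gain k':>8s} {'rob. @ d=0.5':>12s} {'QIC pass':>9s}")
for prom in ("strong", "weak"):
    for gain in ("low", "medium", "high"):
        name = f"{prom}-{gain}-regulated"
        p = fixtures(name)
        rob = robustness(p, "regulated", 0.5).robustness
        rep = qic_check(p)
        print(f"{name:28s} {p.k:8.3f} {rob:11.1f}% {str(rep.passes):>9s}")

rep = qic_check(fixtures("strong-high-regulated"))
print(
    "\nQIC ratios for strong-high-regulated: "
    f"delta/lambda = {rep.r_lambda:.3f}, delta/T = {rep.r_T:.3f}, "
    f"delta/(k*Ts) = {rep.r_gain:.3f} (all must be << 1; threshold {rep.epsilon})"
)
print(
    "Robustness (perturbed/nominal output x 100) increases low -> medium -> "
    "high gain for both promoters; only the high-gain devices satisfy all "
    "three quasi-integral conditions."
)
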