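# qicsim experiment configuration template.
# Unknown keys are rejected; every omitted key takes the documented default.
# Run with:  qicsim step --config examples/experiment.yaml

# experiment kind: simulate | step | robustness | sweep | qic-check | silencing
experiment: step

# model variant: regulated | unregulated | ideal | full
variant: regulated

# named device parameter set ({strong|weak}-{low|medium|high}-{regulated|unregulated});
# omit it and give a complete `params` block to define a custom device
fixture: strong-high-regulated

# parameter overrides applied on top of the fixture (hours / nM-like units)
params: {}
#   T: 300.0          # transcription rate constant per DNA copy (nM/h/copy)
#   D: 10.0           # plasmid copy number
#   kappa_gfp: 100.0  # output RBS dissociation constant (nM)
#   kappa_ecf: 15.0   # sensor RBS dissociation constant (nM); gain k = kappa_gfp/kappa_ecf
#   Ts: 20.0          # lumped sRNA transcription rate constant (1/h per unit sensor)
#   delta: 8.0        # uncoupled mRNA/sRNA decay rate (1/h)
#   lam: 800.0        # coupled mRNA-sRNA decay rate (1/h)
#   beta: 10.0        # mRNA-sRNA binding dissociation constant (nM)
#   R: 1000.0         # maximum translation rate constant (nM/h)
#   gamma: 1.4        # protein decay/dilution rate (1/h)
#   actuator_saturation: null  # half-saturation of sRNA transcription (nM); null = linear

# promoter regulation H(u1): constitutive | activation | repression (Hill K, n)
regulation: {kind: constitutive, K: 1.0, n: 1.0}

# piecewise-constant disturbance d(t) with 0 <= d < 1: either a constant
# {d: 0.5} or breakpoints/values ({breakpoints: [0.0], values: [0.0, 0.5]})
disturbance: {d: 0.5}

u1: 0.0            # transcription-factor input to H(u1)
t_span: [0.0, 10.0]  # integration window (h) for `simulate`
horizon: 10.0      # post-step window (h) for `step`
d_active: 0.5      # perturbed disturbance for robustness/sweeps
epsilon: 0.1       # quasi-integral threshold for "much less than 1"

# sweep axis: gain | disturbance | input
sweep: {axis: gain, values: [0.5, 1.0, 2.0, 4.0, 8.0]}

# open-loop silencing dose response
silencing: {doses: [0, 10, 30, 100, 300], K_half: 30.0, hill_n: 2.0, basal: 0.0, sensor_max: 300.0}

solver: {rtol: 1.0e-8, atol: 1.0e-10, points_per_segment: 500}

seed: null         # used only by randomized property-test helpers
output: null       # CSV/JSON destination; null prints to stdout
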