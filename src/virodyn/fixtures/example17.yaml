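# Worked example A: logistic target-cell growth, exponential-shift
# incidence f = β·x·((v − b1)·e^{−c1·v} + b1), identity removals.
# CTL-only regime at τ3 = 0 (R2 > 1, R4 < 1).
# The source parameter list labels the antibody activation rate "g";
# it is the model's r (r = 1.5 reproduces R4 = 0.2854).
growth:
  form: logistic
  params: {lam: 10.0, d: 0.01, r1: 0.6, K: 500.0}
incidence:
  form: exp_shift
  params: {beta: 0.3, b1: 0.01, c1: 0.01}
removals:
  g1: {form: identity}
  g2: {form: identity}
  g3: {form: identity}
  g4: {form: identity}
rates:
  a: 0.5
  b: 0.15
  c: 0.1
  k: 0.4
  u: 3.0
  p: 1.0
  q: 1.0
  r: 1.5
  h: 1.0
  m1: 0.01
  m2: 0.01
delays:
  tau1: 2.0
  tau2: 5.0
  tau3: 0.0
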