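# Worked example B: linear target-cell growth, Crowley–Martin incidence
# f = β·x·v/((1 + a1·x)(1 + b1·v)), identity removals.
# Coexistence regime at τ3 = 0 (R3 > 1, R4 > 1).
growth:
  form: linear
  params: {lam: 10.0, d: 0.01}
incidence:
  form: crowley_martin
  params: {beta: 0.25, a: 0.01, b: 0.01}
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
  h: 0.1
  m1: 0.01
  m2: 0.01
delays:
  tau1: 5.0
  tau2: 8.0
  tau3: 0.0
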