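# Travelling bump on the torus outer equator (reduced desk-scale run).
domain:
  kind: torus
  R: 4.5
  r: 2.0
mesh:
  builtin: torus
  n_theta: 48
  n_phi: 96
model:
  A: 2.0
  B: 0.4
  h: 0.8
  tau: 3.0
  beta: 5.0
init:
  kind: torus
  u_center: [0.0, 0.0]
  u_extent: [1.0, 0.3077]   # ~2 x 2 length units at the outer equator
  u_level: 2.0
  a_center: [0.0, 0.3077]
  a_extent: [1.0, 0.3077]
  a_level: 1.5
integration:
  T: 400.0
  rtol: 1.0e-6
  atol: 1.0e-6
  output_stride: 1.0
  snapshot_stride: 50
distances:
  backend: fast_marching
seed: 1
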