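# Desk-scale default configuration.
#
# The cell model encodes the neonatal modifications of the
# Beeler-Reuter kinetics (fast inward 2.4 vs 4, slow inward 0.045 vs
# 0.09, inward rectifier suppressed by k_k1_base*(1-alpha)); the
# kinetic speed-ups are the calibrated repolarization scalings under
# which the medium sustains stationary rotating spirals.

cell:
  g_na: 2.4
  g_s: 0.045
  k_k1_base: 0.5
  x1_speedup: 6.0
  d_speedup: 4.0
  f_speedup: 4.0

spiral:                 # settled-spiral preparation for force estimation
  alpha: 0.35
  d_cells: 0.1
  n: 100
  h: 0.025
  dt: 0.05

b2:                     # electrophoretic-drift probe (uses alpha=0.3, d=0.2 best)
  e_list: [-0.0004, -0.0002, 0.0002, 0.0004]
  n_periods: 5.0

grad:
  grad_list: [-0.003, -0.0015, 0.0015, 0.003]
  n_periods: 5.0

disk:
  delta_alpha: -0.05
  r0: 6.0
  d_list: [10.0, 13.0, 16.0, 24.0]

border:                 # moving border zone, 2D desk scale
  nx: 64
  ny: 64
  nz: 1
  h: 0.025
  d_top: 0.2
  d_bottom: 0.0
  alpha_top: 0.45
  alpha_bottom: 0.0
  band_width: 16.0
  alpha_shift: 16.0
  nu: 0.25
  u_cells: -0.04
  dt: 0.05

escape:
  speeds: [-0.01, -0.02, -0.04, -0.08, -0.15]
  n_seeds: 5

transition:
  alpha_list: [0.45, 0.5]
  nu_bracket: [0.05, 0.8]
  d_cells: 0.005
  grid_shape: [28, 28]
  trials: 3
  duration: 2200.0

pinning:
  alpha: 0.35
  d_cells: 0.1
  n: 100
  e_advect: 0.0001
  duration: 2600.0
  disks:
    - {dx: 14.0, dy: 12.0, delta_alpha: -0.30, radius: 8.0}
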