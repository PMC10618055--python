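r_f: 20.0
N0: 150
h_fus: 18.0
h_fis: 60.0
gamma: 0.0001
lambda: 0.02
rho_d: 0.001
rho_g: 0.001
phi1: 0.05
phi2: 0.005
r1: 20.0
r2: 50.0
sigma: 0.4
dt: 1.0
mode: progressive
c: 3
Q: 16
w_env: 1.0
kappa: 0.25
barrier_sigma_floor: 0.05
d_rep: 10.0
a_rep: 5.0
l_rep: 5.0
a_att: 5.0
l_att: 25.0
f_max: 2.0
move_threshold: 2.0
N0_population_range: null
horizon_months: 24000
seed: 0
start_bp: 120000.0
burn_in_months: 6000
traj_stride_months: 12
metrics_stride_months: 120
log_cultural_events: false
landscape:
  kind: synthetic
  shape:
  - 100
  - 100
  cell_size: 5.0
  n_slices: 8
  smoothness: 60.0
  seed: 1234
  slice_years: 250.0
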