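# Versioned default configuration.  The `model` block carries the cited
# wild-type kinetic constants of the Min oscillator in effective 1-d units
# (bulk rates converted with the surface-to-volume factor 2/r, r = 0.5 um);
# swap this file to re-parameterize without code changes.
config_version: 1
model:
  D_D: 2.5            # um^2/s cytosolic MinD diffusion
  D_E: 2.5            # um^2/s cytosolic MinE diffusion
  D_m: 0.0            # um^2/s membrane-species diffusion
  sigma_D: 0.1        # 1/s basal MinD membrane binding (0.025 um/s * 2/r)
  sigma_dD: 0.0019099 # um/s per (molec/um) cooperative recruitment (0.0015 um^3/s / pi r^2)
  sigma_E: 0.1184134  # um/s per (molec/um) MinE recruitment (0.093 um^3/s / pi r^2)
  sigma_de: 0.7       # 1/s MinDE hydrolysis/detachment
  k_exchange: 1.0     # 1/s ADP->ATP nucleotide exchange
  dens_D: 785.0       # molec/um total MinD (1000 /um^3 * pi r^2)
  dens_E: 275.0       # molec/um total MinE (wild-type MinE/MinD = 0.35)
  geometry_factor: 4.0
grid:
  dx: 0.05            # um
run:
  t_end: 600.0        # s
  sample_dt: 1.0      # s
  burn_in: 200.0      # s
  perturbation: 0.01
  seed: 0
occupancy:
  window_w: 0.5       # um
  threshold_mode: fraction_of_spatial_mean
  theta: 0.65
  burn_in: 200.0
induction:
  minE_initial: 1.0
  minE_final: 3.0
  t_c: 4.0            # generations after induction to half-rise
  t_s: 1.5
  time_unit: generations
growth:
  alpha: 0.027726     # 1/min (25-min doubling time)
  tau: 18.0           # min from stable ring to division
  lopt_a: 1.5         # um; L_stable = lopt_a + lopt_b * (R/R0)
  lopt_b: 1.0         # um per unit relative ratio
synth:
  n_lineages: 10
  n_generations: 20
  alpha_cv: 0.05
  tau_cv: 0.05
  lstable_cv: 0.05
  division_fraction_sd: 0.03
  induction_start_gen: 10
  sampling_interval: 1.0
  ring_plateau: 100.0
  ring_rate_post: 2.5
  intensity_noise_sd: 2.0
  background_mean: 5.0
analysis:
  threshold_fraction: 0.65
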