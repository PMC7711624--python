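# Replication study: every constant at its characterized value, all three
# datasets from the seeded generators.  This file spells out the built-in
# defaults of buccalfilm.config.default_study_config() for editing.
seed: 1
outdir: results/study

release:
  model: peppas_sahlin           # generating model for the synthetic curve
  params: {k1: -10.912, k2: 5.571, m: 0.404}
  t_end: 64.0                    # min; release plateaus here
  dt: 2.0                        # min between collected aliquots
  noise: {sd: 1.5, seed: 1}      # % of dose, per point
  cap_at_100: true

permeation:
  flux: 0.237                    # mg/(cm^2 h) steady-state generating slope
  lag_h: 0.0
  breakdown_h: 2.5               # h; sink conditions lost afterwards
  t_end_h: 6.0
  dt_h: 1.0
  tau_h: 0.1                     # h; post-breakdown saturation time constant
  noise: {sd: 0.003, seed: 2}    # mg/cm^2 per sample

adhesion:
  contact_times: [10, 15, 20, 30, 40, 50]   # min
  f_max: 0.88                    # N
  rate: 0.065                    # 1/min
  noise: {sd: 0.01, seed: 3}     # N

film:
  total_area: 8.04               # cm^2
  total_mass_g: 1.03
  thickness_um: 793.0
  disk_area: 0.2827              # cm^2, from the 0.6 cm disk diameter
  disk_mass_mg: 30.94
  dl_pct: 7.40                   # % w/w
  disk_dose_mg: 2.29
  disk_diameter_mm: 6.0
  release_disk_diameter_mm: 11.0

franz:
  acceptor_volume: 15.0          # mL
  sample_volume: 0.5             # mL
  diffusion_area: 0.636          # cm^2
  orifice_diameter: 9.0          # mm

pk:
  cp_ss_per_mg: 1.0              # ng/mL at steady state per mg oral PR dose
  t_half: 6.0                    # h
  v_d_per_kg: 7.5                # L/kg
  body_mass: 70.0                # kg
  exact_ln2: false               # use the conventional 0.693
  oral_doses: [4.0, 8.0]         # mg reference doses to bridge against
  area_multiplier: 1.0           # >1 if both film faces absorb

fit:
  models: [zero_order, first_order, higuchi, hopfenberg, power_law,
           peppas_sahlin]
  fit_range: to_plateau
  geometry: film
  flux_r2_threshold: 0.99
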