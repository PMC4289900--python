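# Example study configuration for `dendromaps run`.
#
# A desk-scale study: synthetic 6 mm CA1-like cell, 1 mm atrophy steps,
# passive and HCN-gradient backgrounds, maps at the three canonical trunk
# sites, influence fields on three members.  For the full-size study set
# target_total_length: 17.5 (runtime grows accordingly).

seed: 1
synthetic:
  target_total_length: 6.0

prune_step_mm: 1.0
prune_floor_mm: 1.0
stratum_width_um: 50.0

passive: {}        # PassiveProfile defaults (R_m 55->20 kOhm*cm^2, ...)
hcn: {}            # HcnDistribution defaults (50 uS/cm^2, 25-fold gradient)
kinetics: {}       # HcnKinetics defaults

dt_ms: 0.1
chirp_duration_s: 10.0
chirp_amplitude_pa: 50.0
rin_reduced_range: true

site_radial_um: [0.0, 150.0, 300.0]

influence_enabled: true
influence_members: 3
influence_sites: 10

output_dir: results/example_study
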