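# Full study configuration: WT vs rhodopsin-hemizygote mouse cohorts.
# discs_per_animal: 25 reproduces the published imaging design
# (3 animals x 25 outer segments per genotype); the default here is
# smaller for quick runs.
seed: 1
calibration_genotype: WT
census:
  rhodopsin_per_rod: 60000000.0
  discs_per_rod: 800
uncertainty:
  n_draws: 10000
  ci_level: 0.95
detection:
  closing_radius: 15
  min_incisure_length_fraction: 0.03
  min_component_area: 20
genotypes:
  WT:
    ratios:
      rho_to_prph2:
        mean: 18.2
        sd: 0.6
        n: 3
      rho_to_rom1:
        mean: 42.2
        sd: 0.6
        n: 3
      prph2_to_rom1:
        mean: 2.3
        sd: 0.1
        n: 3
      rho_to_tetraspanin:
        mean: 12.7
        sd: 0.4
        n: 3
    geometry:
      diameter: 1.5
      incisure_fraction: 0.5
    synthetic:
      n_animals: 3
      discs_per_animal: 8
      pixel_size: 3.0
      noise_sigma: 8.0
      diameter_sd: 0.04
      fraction_sd: 0.02
      incisures:
      - angle: 90.0
        length_fraction: 0.5
        width: 30.0
        shape: straight
  Rho+/-:
    ratios:
      rho_to_prph2:
        mean: 8.5
        sd: 1.5
        n: 3
      rho_to_rom1:
        mean: 21.6
        sd: 3.7
        n: 3
      prph2_to_rom1:
        mean: 2.6
        sd: 0.6
        n: 3
      rho_to_tetraspanin:
        mean: 6.0
        sd: 0.8
        n: 3
    geometry:
      circumference: 3.36
    synthetic:
      n_animals: 3
      discs_per_animal: 8
      pixel_size: 3.0
      noise_sigma: 8.0
      diameter_sd: 0.03
      fraction_sd: 0.05
      incisures:
      - angle: 90.0
        length_fraction: 1.3
        width: 30.0
        shape: twisted
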