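# Example run configuration.
#
# categories maps traits to their metabolic scaling category; expected
# exponents are derived from the metabolic exponent m of each hypothesis:
#   production_rate -> m, biological_time -> 1 - m,
#   biological_rate -> m - 1, biomass_product -> 1.
categories:
  clutch_volume: biomass_product
  juvenile_mass: biomass_product
  annual_clutch_volume: production_rate
  annual_clutch_number: biological_rate
  incubation_time: biological_time
  larval_period: biological_time
  age_at_maturity: biological_time
  max_longevity: biological_time

metabolic_exponents:
  MDH: 0.88   # amphibian-specific metabolic scaling exponent
  MTE: 0.75   # Kleiber's law

alpha: 0.05
criterion: REML
lambda_bounds: [-2.0, 2.0]
nsim: 1000
seed: 0

# Length-to-mass power laws (M = a * L^b, L in mm, M in g) are user-supplied;
# the placeholder coefficients below are synthetic examples, not published values.
length_mass_allometries:
  example_family: { a: 0.05, b: 2.5 }
  example_habitat_group: { a: 0.03, b: 2.7 }
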