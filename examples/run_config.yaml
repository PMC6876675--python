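# Full pipeline run configuration.
#
# Input source: either `dgp: default` (synthetic panel from the built-in
# configuration, seeded by `seed`) or `panel_path: <csv>`; exactly one.
dgp: default
seed: 1

# probit covariates (baseline values); log_vars are log-transformed first
covariates:
  - male_head
  - age_head
  - farming
  - casual_labour
  - educ_share
  - valley_bottom
  - cassava_disease
  - land_ha
  - assets_usd
  - mwanza
log_vars: [age_head, assets_usd]

# outcomes to estimate IPW-DID effects for (panel or indicator columns)
outcomes: [adoption, knowledge, hdds_latent, relief_months]
placebo_outcomes: [knowledge, hdds_latent, relief_months]

algorithm: radius           # nearest_neighbour | radius | kernel
algorithm_params:
  radius: 0.05
support_convention: intersection   # or treated_preserving
use_ipw: true

out_dir: runs/example
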