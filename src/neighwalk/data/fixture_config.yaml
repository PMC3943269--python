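# Desk-scale demonstration configuration: 100 contiguous tracts with
# ~20 residents each, environmental effects amplified so that the
# exposures carry most of the spatially structured outcome variation.
generator:
  lattice_rows: 10
  lattice_cols: 10
  n_per_neighborhood: 20
  vary_n: true
  sigma_u: 0.15
  tau_v: 0.10
  env_spatial_range: 3
  missing_rate: 0.02
  seed: 20070101
  true_betas:
    sex_male[1]: 0.3221
    employment[3]: 0.5188
    temp_cat[3]: 0.3365
    temp_cat[4]: 0.3148
    nbhd_education[2]: 0.26
    nbhd_education[3]: 0.55
    nbhd_education[4]: 0.75
    air_traffic[1]: -0.56
    density_destinations[4]: 0.45
  true_betas_ordinal:
    sex_male[1]: 0.2469
    employment[3]: 0.6366
    nbhd_education[3]: 0.40
    nbhd_education[4]: 0.55
    green_space_quality[4]: 0.60
    air_traffic[1]: -0.45
    density_destinations[4]: 0.50
mcmc:
  n_iter: 1600
  n_burnin: 600
  thin: 2
n_boot: 100
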