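alpha_shape1_loc: 4.0
alpha_shape1_scale: 1.0
alpha_shape2_loc: 7.0
alpha_shape2_scale: 3.0
beta_group_mean_loc: 0.65
beta_group_mean_scale: 1.0
beta_group_sd_shape: 2.0
beta_group_sd_rate: 1.0
beta_lower: -1.5
beta_upper: 1.5
gamma_log_loc: 0.0
gamma_log_scale: 0.25
delta_shape_loc: 2.0
delta_shape_scale: 1.0
delta_shape_lower: 1.0
nu_group_mean_loc: 4.0
nu_group_mean_scale: 2.0
nu_group_sd_shape: 3.0
nu_group_sd_rate: 1.0
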