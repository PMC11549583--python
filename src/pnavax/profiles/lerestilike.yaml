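# Synthetic study profile "lerestilike", version 1.
# Entirely synthetic: mirrors the published marginal summaries of a rural
# Romanian personal-network vaccination study (attribute means, network
# density, missingness, assortative referrals) -- no real microdata involved.
n_egos: 83
alter_size_weights: {15: 1, 20: 3, 22: 2, 23: 2, 24: 4, 25: 52}
target_density: 0.65
density_sd: 0.21
ego_age_mean: 53.33
ego_age_sd: 15.86
p_ego_female: 0.52
ego_education_mean: 9.70
ego_education_sd: 1.78
p_ego_single: 0.125
p_ego_employed: 0.5625
p_ego_vaccinated: 0.78
media_probs: [0.17, 0.34, 0.49]
alter_age_mean: 52.64
alter_age_sd: 16.06
p_alter_female: 0.525
alter_education_mean: 9.35
alter_education_sd: 1.93
p_alter_single: 0.20
vaccination_base_logit: 0.0
coef_alter_education: 0.6
coef_alter_single: -0.4
coef_alter_age: 0.0
coef_alter_sex: 0.0
coef_media_online: -1.0
coef_media_both: -0.3
coef_ego_vaccinated: 1.3
sigma_ego: 0.9
tie_homophily: 0.22
contagion_rounds: 0
contagion_strength: 1.5
missing_alter_vaccination: 0.1127
missing_ego_media: 0.036
missing_alter_education: 0.033
n_seeds: 6
referral_concordance: 0.76
refusal_rate: 0.458
max_referrals: 3
seed: 0
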