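# Anderson et al. (1991) combined cardiovascular disease equation, Weibull
# accelerated failure time parameterisation as used in the New Zealand
# absolute-risk charts:
#   mu    = intercept + sum(coef * covariate)
#   sigma = exp(sigma_const + sigma_mu * mu)
#   u     = (ln(t) - mu) / sigma,  t = 5 years
#   p     = 1 - exp(-exp(u))
# Covariates: female (0/1), ln_age (ln years), female_ln_age, ln_sbp (ln mmHg),
# smoker (0/1), ln_tc_hdl_ratio (ln of total:HDL cholesterol ratio),
# diabetes (0/1), female_diabetes, lvh (left-ventricular hypertrophy on ECG,
# 0/1; defaults to absent, no survey field collects it).
term,value
intercept,18.8144
female,-1.2146
ln_age,-1.8443
female_ln_age,0.3668
ln_sbp,-1.4032
smoker,-0.3899
ln_tc_hdl_ratio,-0.5390
diabetes,-0.3036
female_diabetes,-0.1697
lvh,-0.3362
sigma_const,0.6536
sigma_mu,-0.2402
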