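# Framingham general cardiovascular disease risk equations (lipid-based Cox model,
# D'Agostino et al., Circulation 2008;117:743-53), sex-specific.
# 10-year risk = 1 - S0 ^ exp(sum(beta_i * x_i) - mean_lp), with log-transformed
# continuous covariates. Valid ages 30-74; outside that range inputs are clamped.
# The combined CVD risk is split into CHD and stroke via chd_stroke_split_ratio.
version: "2008-general-cvd-lipids"
functional_form: cox_survival
outcome: cvd_combined
chd_stroke_split_ratio: 3.0   # CHD events per stroke event (configurable)
coefficients:
  male:
    ln_age: 3.06117
    ln_total_cholesterol: 1.12370
    ln_hdl: -0.93263
    ln_sbp_untreated: 1.93303
    ln_sbp_treated: 1.99881
    smoker: 0.65451
    diabetic: 0.57367
    baseline_survival: 0.88936
    mean_lp: 23.9802
  female:
    ln_age: 2.32888
    ln_total_cholesterol: 1.20904
    ln_hdl: -0.70833
    ln_sbp_untreated: 2.76157
    ln_sbp_treated: 2.82263
    smoker: 0.52873
    diabetic: 0.69154
    baseline_survival: 0.95012
    mean_lp: 26.1931
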