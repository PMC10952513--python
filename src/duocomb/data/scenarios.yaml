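# Default simulation truth (synthetic, calibrated — no external data).
#
# Toxicity profiles: two parameter sets judged plausible for a
# cisplatin/cabazitaxel-type combination; each interaction value is solved
# so that the true MTD curve at theta_T = 0.33 passes through the
# standardized anchor (1/3, 1/2), i.e. 15/75 mg/m2 on the raw scales
# 10-25 / 50-100 mg/m2.
#
# Efficacy profiles: shape controls for the stage-II dose-efficacy surface,
# per toxicity profile (the curve geometry decides how steep the composed
# profile can be).  peak_frac locates the most efficacious combination
# along the MTD curve (0 = low-x end, 1 = high-x end); the two profiles
# put it at opposite ends.  beta2/beta3 set the shape away from the peak
# and endpoint_contrast the logit gap between the favoured and the
# opposite end, so that part of the curve falls below the standard-of-care
# response rate.  The intercept and the X main effect are calibrated at
# run time so the peak response hits p0 + effect_size (H1) or p0 (H0).
toxicity_profiles:
  - rho00: 0.01
    rho01: 0.20
    rho10: 0.20
    alpha3: 7.2775
  - rho00: 0.005
    rho01: 0.35
    rho10: 0.15
    alpha3: 6.3705
efficacy_profiles:
  tox1:
    - peak_frac: 0.0
      beta2: 1.5
      beta3: 5.0
      endpoint_contrast: 1.5
    - peak_frac: 1.0
      beta2: 1.5
      beta3: 5.0
      endpoint_contrast: 1.5
  tox2:
    - peak_frac: 0.0
      beta2: 1.5
      beta3: 2.0
      endpoint_contrast: 1.5
    - peak_frac: 1.0
      beta2: 1.5
      beta3: 2.0
      endpoint_contrast: 1.5
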