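{
  "comment": "Published TRIMP probit coefficients with robust standard errors, refit on 199,840 patients. Feature order matches trimp.model.FEATURE_NAMES.",
  "n_fit": 199840,
  "coefficients": {
    "constant": {"estimate": -7.87668, "robust_se": 0.22814},
    "wmdp1": {"estimate": 1.74286, "robust_se": 0.05855},
    "wmdp2": {"estimate": 0.90205, "robust_se": 0.14902},
    "wmdp3": {"estimate": 0.48395, "robust_se": 0.08800},
    "wmdp4": {"estimate": 0.24008, "robust_se": 0.12063},
    "wmdp5": {"estimate": 0.52620, "robust_se": 0.11745},
    "interaction": {"estimate": -0.14533, "robust_se": 0.06401},
    "same_region": {"estimate": -0.16288, "robust_se": 0.04142},
    "nbr": {"estimate": 0.09595, "robust_se": 0.01685},
    "nbr_fp": {"estimate": -1.84530, "robust_se": 0.17565},
    "age": {"estimate": 0.04249, "robust_se": 0.00102},
    "male": {"estimate": 0.13122, "robust_se": 0.03725},
    "cci": {"estimate": 0.29517, "robust_se": 0.02260},
    "mechanism": {"estimate": 0.15933, "robust_se": 0.01981},
    "gcs": {"estimate": -0.11159, "robust_se": 0.00440},
    "icu": {"estimate": 0.20514, "robust_se": 0.05609},
    "vent": {"estimate": 1.76084, "robust_se": 0.05315},
    "sbp_code": {"estimate": 0.39901, "robust_se": 0.01841},
    "pulse_code": {"estimate": 0.27502, "robust_se": 0.01752},
    "rr_code": {"estimate": 0.09428, "robust_se": 0.01319}
  }
}
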