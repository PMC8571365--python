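{
  "comment": "TRISS logistic survival-model constants per the Boyd (1987) MTOS methodology: b = b0 + b1*RTS + b2*ISS + b3*AgeIndex per mechanism class, P(survival) = 1/(1+exp(-b)). AgeIndex is the classic binary coding (0 if age <= 54, 1 otherwise). RTS weights apply to the standard 0-4 coded GCS/SBP/RR. A user JSON of the same shape (optionally with 'age_bands' of [lo, hi, index] triples replacing 'age_threshold') may be supplied to use revised coefficient vintages.",
  "vintage": "1987-MTOS",
  "rts_weights": {"gcs": 0.9368, "sbp": 0.7326, "rr": 0.2908},
  "age_threshold": 54,
  "blunt": {"b0": -1.2470, "b_rts": 0.9544, "b_iss": -0.0768, "b_age": -1.9052},
  "penetrating": {"b0": -0.6029, "b_rts": 1.1430, "b_iss": -0.1516, "b_age": -2.6676}
}
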