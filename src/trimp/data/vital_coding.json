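{
  "comment": "Default ordinal derangement codes for systolic blood pressure (mmHg), pulse rate (beats/min) and respiratory rate (breaths/min). 0 = physiologically normal; larger = worse, so the positive model coefficients for SBP/pulse/RR raise predicted mortality with derangement. Intervals are [lo, hi] inclusive, hi = null means unbounded; a measurement is assigned the code of the first interval whose upper bound it does not exceed. SBP and RR reverse the conventional Revised-Trauma-Score bins; the pulse table is an analogous two-sided (brady/tachycardia) convention. Fully configurable.",
  "sbp": [[0, 0, 4], [1, 49, 3], [50, 75, 2], [76, 89, 1], [90, null, 0]],
  "pulse": [[0, 0, 4], [1, 39, 3], [40, 49, 1], [50, 119, 0], [120, 149, 1], [150, null, 2]],
  "rr": [[0, 0, 4], [1, 5, 3], [6, 9, 2], [10, 29, 0], [30, null, 1]]
}
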