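{
  "comment": "ICD-9-CM external-cause (E-code) ranges per injury-mechanism family, grouped per the CDC external-cause-of-injury matrix. Ranges are inclusive on the numeric part after the leading 'E' (a fourth digit is the decimal). Codes matching no family are treated as nontraumatic/excluded mechanisms.",
  "families": {
    "1": {
      "name": "stab",
      "ranges": [[920.0, 920.9], [956.0, 956.9], [966.0, 966.9], [974.0, 974.9], [986.0, 986.9]]
    },
    "2": {
      "name": "violence",
      "ranges": [[960.0, 961.9], [965.5, 965.9], [967.0, 968.9], [973.0, 973.9], [975.0, 975.9]]
    },
    "3": {
      "name": "blunt",
      "ranges": [[800.0, 807.9], [826.0, 829.9], [840.0, 845.9], [916.0, 919.9], [921.0, 921.9], [923.0, 923.9]]
    },
    "4": {
      "name": "fall",
      "ranges": [[880.0, 888.9], [957.0, 957.9], [987.0, 987.9]]
    },
    "5": {
      "name": "motor_vehicle",
      "ranges": [[810.0, 825.9]]
    },
    "6": {
      "name": "firearm",
      "ranges": [[922.0, 922.9], [955.0, 955.4], [965.0, 965.4], [970.0, 970.9], [985.0, 985.4]]
    }
  },
  "excluded_examples": {
    "poisoning": [[850.0, 869.9]],
    "fire_burn": [[890.0, 899.9], [924.0, 924.9]],
    "drowning": [[910.0, 910.9]],
    "suffocation": [[911.0, 913.9]],
    "overexertion": [[927.0, 927.9]]
  }
}
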