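{
  "comment": "Deyo ICD-9-CM adaptation of the Charlson Comorbidity Index. Each condition lists diagnosis-code prefixes (dots stripped); a patient code matches a condition if it starts with any prefix. Each condition is counted once. Hierarchies: complicated diabetes supersedes uncomplicated; moderate/severe liver disease supersedes mild; metastatic solid tumour supersedes any malignancy.",
  "conditions": {
    "myocardial_infarction": {"weight": 1, "prefixes": ["410", "412"]},
    "congestive_heart_failure": {"weight": 1, "prefixes": ["428"]},
    "peripheral_vascular_disease": {"weight": 1, "prefixes": ["4439", "441", "7854", "V434"]},
    "cerebrovascular_disease": {"weight": 1, "prefixes": ["430", "431", "432", "433", "434", "435", "436", "437", "438"]},
    "dementia": {"weight": 1, "prefixes": ["290"]},
    "chronic_pulmonary_disease": {"weight": 1, "prefixes": ["490", "491", "492", "493", "494", "495", "496", "500", "501", "502", "503", "504", "505", "5064"]},
    "rheumatologic_disease": {"weight": 1, "prefixes": ["7100", "7101", "7104", "7140", "7141", "7142", "71481", "725"]},
    "peptic_ulcer_disease": {"weight": 1, "prefixes": ["531", "532", "533", "534"]},
    "mild_liver_disease": {"weight": 1, "prefixes": ["5712", "5714", "5715", "5716"]},
    "diabetes": {"weight": 1, "prefixes": ["2500", "2501", "2502", "2503", "2507"]},
    "diabetes_with_complications": {"weight": 2, "prefixes": ["2504", "2505", "2506"]},
    "hemiplegia_paraplegia": {"weight": 2, "prefixes": ["342", "3441"]},
    "renal_disease": {"weight": 2, "prefixes": ["582", "5830", "5831", "5832", "5833", "5834", "5835", "5836", "5837", "585", "586", "5880"]},
    "any_malignancy": {"weight": 2, "prefixes": ["140", "141", "142", "143", "144", "145", "146", "147", "148", "149", "150", "151", "152", "153", "154", "155", "156", "157", "158", "159", "160", "161", "162", "163", "164", "165", "166", "167", "168", "169", "170", "171", "172", "174", "175", "176", "177", "178", "179", "180", "181", "182", "183", "184", "185", "186", "187", "188", "189", "190", "191", "192", "193", "194", "195", "200", "201", "202", "203", "204", "205", "206", "207", "208"]},
    "moderate_severe_liver_disease": {"weight": 3, "prefixes": ["4560", "4561", "4562", "5722", "5723", "5724", "5728"]},
    "metastatic_solid_tumor": {"weight": 6, "prefixes": ["196", "197", "198", "199"]},
    "aids": {"weight": 6, "prefixes": ["042", "043", "044"]}
  },
  "hierarchies": [
    ["diabetes_with_complications", "diabetes"],
    ["moderate_severe_liver_disease", "mild_liver_disease"],
    ["metastatic_solid_tumor", "any_malignancy"]
  ]
}
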