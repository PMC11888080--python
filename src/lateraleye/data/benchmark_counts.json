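{
  "description": "Reference contingency counts for the two discordant-laterality subgroups (left-side procedure with right-side diagnoses, LR; right-side procedure with left-side diagnoses, RL) from a published clinical review of 2020 US inpatient orthopedic claims: per-method flagged counts with confirmed error / nonerror subcategory breakdowns.",
  "rule": {
    "LR": {
      "flagged": 1106,
      "error_kinds": {"SAME_BODY_PART": 421, "DIFFERENT_BODY_PART": 182},
      "nonerror_kinds": {
        "UNSPECIFIED_SIDE": 39,
        "NO_LATERALITY": 131,
        "GENERAL_DIAGNOSIS": 251,
        "PROXIMITY": 4,
        "COMBINATION": 78
      }
    },
    "RL": {
      "flagged": 1064,
      "error_kinds": {"SAME_BODY_PART": 390, "DIFFERENT_BODY_PART": 151},
      "nonerror_kinds": {
        "UNSPECIFIED_SIDE": 50,
        "NO_LATERALITY": 271,
        "GENERAL_DIAGNOSIS": 129,
        "PROXIMITY": 4,
        "COMBINATION": 69
      }
    }
  },
  "aop": {
    "LR": {
      "flagged": 697,
      "error_kinds": {"SAME_BODY_PART": 404, "DIFFERENT_BODY_PART": 172},
      "nonerror_kinds": {
        "UNSPECIFIED_SIDE": 17,
        "NO_LATERALITY": 34,
        "GENERAL_DIAGNOSIS": 58,
        "PROXIMITY": 2,
        "COMBINATION": 10
      }
    },
    "RL": {
      "flagged": 655,
      "error_kinds": {"SAME_BODY_PART": 376, "DIFFERENT_BODY_PART": 148},
      "nonerror_kinds": {
        "UNSPECIFIED_SIDE": 17,
        "NO_LATERALITY": 75,
        "GENERAL_DIAGNOSIS": 25,
        "PROXIMITY": 4,
        "COMBINATION": 10
      }
    }
  }
}
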