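{
  "_comment": "Built-in 9-position pocket preference profile for the fallback binding-core predictor: a transparent position-weight scorer rewarding hydrophobic residues at the P1/P4/P6/P9 pockets and mildly penalising proline inside the core. Keys are core positions 1-9; unlisted residues score 0. This is a naive stand-in contract-compatible with external core predictors.",
  "profile": {
    "1": {"F": 5, "W": 5, "Y": 5, "I": 4, "L": 4, "V": 3, "M": 3, "P": -2},
    "2": {"P": -1},
    "3": {"P": -1},
    "4": {"F": 3, "W": 3, "Y": 3, "I": 3, "L": 3, "V": 2, "M": 2, "D": 1, "E": 1, "P": -2},
    "5": {"P": -1},
    "6": {"I": 3, "L": 3, "V": 3, "A": 2, "T": 1, "S": 1, "P": -2},
    "7": {"P": -1},
    "8": {"P": -1},
    "9": {"F": 3, "W": 3, "Y": 3, "I": 3, "L": 4, "V": 3, "M": 3, "K": 1, "P": -2}
  }
}
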