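{
  "PA": {
    "3-Hydroxypropionic acid": 6.0,
    "Methylcitric acid": 6.0,
    "AC_C3": 6.0
  },
  "MMA": {
    "Methylmalonic acid": 6.0,
    "Methylcitric acid": 4.0,
    "AC_C3": 4.0,
    "AC_C4DC": 6.0
  },
  "IVA": {
    "Isovalerylglycine": 6.0,
    "AC_C5": 6.0
  },
  "MCC": {
    "3-Hydroxyisovaleric acid": 6.0,
    "3-Methylcrotonylglycine": 6.0,
    "AC_C5OH": 6.0
  },
  "GA2": {
    "Glutaric acid": 6.0,
    "2-Hydroxyglutaric acid": 6.0,
    "AC_C8": 4.0,
    "AC_C10": 4.0,
    "AC_C14": 4.0
  },
  "MCAD": {
    "AC_C8": 6.0,
    "AC_C6": 4.0,
    "Hexanoylglycine": 4.0
  },
  "VLCAD": {
    "AC_C14:1": 6.0,
    "AC_C14": 4.0
  },
  "CPT2": {
    "AC_C16": 6.0,
    "AC_C18": 6.0,
    "AC_C18:1": 4.0
  },
  "TFP": {
    "AC_C16OH": 6.0,
    "AC_C18:1OH": 6.0
  },
  "PKU": {
    "Phenylalanine": 6.0,
    "Tyrosine": -4.0
  },
  "OTC": {
    "Glutamine": 6.0,
    "Citrulline": -4.0
  }
}
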