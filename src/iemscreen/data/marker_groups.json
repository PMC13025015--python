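{
  "group_A": {
    "diseases": ["PA", "MMA"],
    "markers": [
      "3-Hydroxypropionic acid",
      "Methylcitric acid",
      "Methylmalonic acid",
      "AC_C3",
      "AC_C4DC"
    ]
  },
  "group_B": {
    "diseases": ["IVA", "MCC"],
    "markers": [
      "Isovalerylglycine",
      "AC_C5",
      "3-Hydroxyisovaleric acid",
      "3-Methylcrotonylglycine",
      "AC_C5OH"
    ]
  },
  "group_C": {
    "diseases": ["VLCAD", "CPT2", "TFP"],
    "markers": [
      "AC_C14:1",
      "AC_C14",
      "AC_C16",
      "AC_C18",
      "AC_C18:1",
      "AC_C16OH",
      "AC_C18:1OH"
    ]
  }
}
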