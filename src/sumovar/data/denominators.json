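{
  "variants_total": 68779,
  "disease": 24399,
  "polymorphism": 37878,
  "unclassified": 6502,
  "proteins": 12512,
  "independent_test": {"TP": 29, "FN": 4, "TN": 27, "FP": 6}
}
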