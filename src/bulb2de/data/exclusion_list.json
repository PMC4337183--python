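{
  "comment": "Default m/z exclusion list for MALDI PMF peak matching: porcine trypsin autolysis products ([M+H]+, monoisotopic) and common CHCA matrix cluster ions. Editable; pass a custom list to match_peaks to override.",
  "trypsin_autolysis": [842.5094, 1045.5637, 2211.1040, 2283.1802],
  "matrix_clusters": [190.0499, 212.0318, 379.0925, 568.1366, 757.1807]
}
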