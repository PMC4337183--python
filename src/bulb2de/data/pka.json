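{
  "comment": "EMBOSS pKa set for protein ionizable groups. 'basic' groups are positively charged below their pKa; 'acidic' groups negatively charged above. Any consistent published set works; this one is the EMBOSS iep default.",
  "basic": {"nterm": 8.6, "H": 6.5, "K": 10.8, "R": 12.5},
  "acidic": {"cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}
}
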