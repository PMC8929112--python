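# NLR class-assignment motif rules (regular expressions over the protein
# sequence). These are synthetic fixture motifs standing in for the
# N-terminal domain signatures used in the field: a TIR block motif, an
# RPW8-like coiled-coil signature (CCR), the CC-domain EDVID motif, and the
# LxxLxL leucine-rich-repeat rule. They are data, not code: edit this file
# (or pass --motifs) to change classification behaviour.
motifs:
  tir: "[FY]LSFRG[EP]DT"
  ccr: "CADLQEL"
  cc: "EDV[IL]D"
  lrr: "L..L.L"
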