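# Published qPCR fold changes for ectopic Cut expression in Class I
# neurons relative to driver-only controls, reference gene RpL32.
reference_gene: RpL32
control_condition: control
case_condition: ct-OE
folds:
  bdwf: 4.0   # reported four-fold increase in bdwf mRNA
  ct: 14.0    # reported ~14-fold increase in ct mRNA
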