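# Published Cut-overexpression hypertrophy in Class I vpda neurons:
# fold change of the case group mean relative to control.
ct-OE:
  tdl_fold: 3.0    # reported 3-fold increase in total dendritic length
  tdb_fold: 7.5    # reported "over 7.5-fold" increase in branch count
  n_control: 15
  n_case: 14
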