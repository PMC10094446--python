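# Published cohort-level morphometric effect sizes (percent change from
# control in total dendritic length and total dendritic branches) for
# Drosophila larval da neuron classes under bdwf knockdown (bdwf-IR) and
# bdwf overexpression (bdwf-OE).  These parameterize synthetic condition
# effects: length_scale = 1 + tdl_pct/100, branch_scale = 1 + tdb_pct/100.
CIV:
  bdwf-IR: {tdl_pct: -26.0, tdb_pct: -27.7}   # reported average over ddaC, v'ada, vdaB subtypes
  bdwf-OE: {tdl_pct: -0.1, tdb_pct: -14.3}    # reported TDB effect confined to the ddaC subtype
CIII:
  bdwf-IR: {tdl_pct: -48.5, tdb_pct: -53.0}   # reported for the ddaF subtype
  bdwf-OE: {tdl_pct: -24.1, tdb_pct: -38.2}
CI:
  bdwf-IR: {tdl_pct: -24.7, tdb_pct: -29.6}   # reported average over ddaE, vpda subtypes
  bdwf-OE: {tdl_pct: -14.9, tdb_pct: -12.6}
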