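# Published dendritic branch density (DBD = TDB/TDL) percent changes from
# control.  dbd_pct combines with the class-level size change (tdl_pct,
# from the companion length/branch fixture) to fix the condition scales:
# length_scale = 1 + tdl_pct/100, branch_scale = (1 + dbd_pct/100) * length_scale.
# Non-significant published comparisons are transcribed as 0.0 ("n.s.").
bdwf-IR:
  ddaC:  {class: CIV, dbd_pct: 0.0,  tdl_pct: -26.0}   # n.s.
  v'ada: {class: CIV, dbd_pct: 0.0,  tdl_pct: -26.0}   # n.s.
  vdaB:  {class: CIV, dbd_pct: -9.5, tdl_pct: -26.0}   # only subtype with a reported DBD change
  ddaF:  {class: CIII, dbd_pct: 0.0, tdl_pct: -48.5}   # n.s.
  ddaE:  {class: CI, dbd_pct: 0.0,  tdl_pct: -24.7}    # n.s.
  vpda:  {class: CI, dbd_pct: 0.0,  tdl_pct: -24.7}    # n.s.
bdwf-OE:
  CIII: {dbd_pct: -31.2, tdl_pct: -24.1}    # strongest reported density reduction
  CIV:  {dbd_pct: -14.25, tdl_pct: -0.1}
  CI:   {dbd_pct: 2.5,   tdl_pct: -14.9}    # reported as not significant
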