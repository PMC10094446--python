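# Published microtubule-channel signal reduction relative to control as a
# function of path distance from the soma (Class IV neurons).  Each anchor
# is [path_distance_um, fraction_of_control_lost]; the suppression curve
# s(d) = 1 - reduction(d) interpolates linearly between anchors and is flat
# beyond them.
bdwf-IR:
  anchors: [[20, 0.50], [400, 0.98]]   # ~50% loss at 20 um, near-complete loss by ~400 um
RpS24-IR:
  anchors: [[20, 0.40], [540, 0.77]]   # milder: ~40% loss at 20 um, ~77% at the farthest bin (540 um)
  n_case: 14
  n_control: 10
RpL4-IR:
  anchors: [[20, 0.70], [540, 0.92]]   # ~70% loss at 20 um, progressive distal decline
RpL22-IR:
  anchors: [[20, 0.70], [540, 0.92]]
RpL31-IR:
  anchors: [[20, 0.70], [540, 0.92]]
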