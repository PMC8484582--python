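# Rectangular flow-channel presets (Ibidi µ-slide VI family).
# Dimensions in mm: height is the short (wall-normal) dimension.
ibidi_VI_0.4:
  height_mm: 0.4
  width_mm: 3.8
  length_mm: 17.0
ibidi_VI_0.5:
  height_mm: 0.54
  width_mm: 3.8
  length_mm: 17.0
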