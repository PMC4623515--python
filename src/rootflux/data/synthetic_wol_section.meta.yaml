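pixel_size: 1.5
xylem_axis:
- 1
- 2
- 3
- 4
- 5
protoxylem_pole_angles:
- 0.0
- 180.0
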