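[5, 7, 9, 26, 45, 58, 59, 62, 63, 66, 67, 69, 70, 73, 74, 77, 80, 81, 84, 97, 99, 114, 116, 123, 124, 133, 143, 146, 147, 152, 155, 156, 159, 163, 164, 167, 171]
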