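body_part_a,body_part_b
shoulder,humerus
upper_leg,femur
knee,lower_leg
hip,femur
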