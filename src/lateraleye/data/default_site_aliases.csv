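body_part,site
knee_joint,knee
hip_joint,hip
hip_bursa,hip
shoulder_joint,shoulder
glenoid_cavity,shoulder
femoral_shaft,femur
upper_femur,femur
upper_arm_tendon,upper_arm
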