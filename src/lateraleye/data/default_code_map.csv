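code_or_prefix,system,body_part,laterality,is_general,is_infusion_device_insertion
0SRC,PCS,knee_joint,RIGHT,false,false
0SRD,PCS,knee_joint,LEFT,false,false
0SPD,PCS,knee_joint,LEFT,false,false
0SR9,PCS,hip_joint,RIGHT,false,false
0SRB,PCS,hip_joint,LEFT,false,false
0SPB,PCS,hip_joint,LEFT,false,false
0Y6H,PCS,lower_leg,RIGHT,false,false
0Y6J,PCS,lower_leg,LEFT,false,false
0LS4,PCS,upper_arm_tendon,LEFT,false,false
0RRK,PCS,shoulder_joint,LEFT,false,false
0RRJ,PCS,shoulder_joint,RIGHT,false,false
0PR8,PCS,glenoid_cavity,LEFT,false,false
0PR7,PCS,glenoid_cavity,RIGHT,false,false
0MBL,PCS,hip_bursa,RIGHT,false,false
0MBM,PCS,hip_bursa,LEFT,false,false
0QB8,PCS,femoral_shaft,RIGHT,false,false
0QB9,PCS,femoral_shaft,LEFT,false,false
0QH6,PCS,upper_femur,RIGHT,false,false
0QH7,PCS,upper_femur,LEFT,false,false
0JH,PCS,,NO_LATERALITY,false,true
M1711,CM,knee,RIGHT,false,false
M1712,CM,knee,LEFT,false,false
M1710,CM,knee,UNSPECIFIED_SIDE,false,false
M1611,CM,hip,RIGHT,false,false
M1612,CM,hip,LEFT,false,false
M19021,CM,elbow,RIGHT,false,false
M19022,CM,elbow,LEFT,false,false
M75121,CM,shoulder,RIGHT,false,false
M75122,CM,shoulder,LEFT,false,false
M75120,CM,shoulder,UNSPECIFIED_SIDE,false,false
S42241,CM,humerus,RIGHT,false,false
S42242,CM,humerus,LEFT,false,false
Z4733,CM,knee,NO_LATERALITY,false,false
Z96641,CM,hip,RIGHT,false,false
Z96642,CM,hip,LEFT,false,false
Z89511,CM,lower_leg,RIGHT,false,false
Z89512,CM,lower_leg,LEFT,false,false
S0501,CM,eye,RIGHT,false,false
S0502,CM,eye,LEFT,false,false
H10501,CM,eye,RIGHT,false,false
H10502,CM,eye,LEFT,false,false
C3402,CM,bronchus,LEFT,false,false
C3401,CM,bronchus,RIGHT,false,false
E1152,CM,,NO_LATERALITY,true,false
I96,CM,,NO_LATERALITY,true,false
C7951,CM,,NO_LATERALITY,true,false
T8484,CM,,NO_LATERALITY,true,false
Y792,CM,,NO_LATERALITY,true,false
T8131,CM,,NO_LATERALITY,true,false
T8141,CM,,NO_LATERALITY,true,false
Y838,CM,,NO_LATERALITY,true,false
F17210,CM,,NO_LATERALITY,false,false
E785,CM,,NO_LATERALITY,false,false
I10,CM,,NO_LATERALITY,false,false
E7800,CM,,NO_LATERALITY,false,false
N186,CM,,NO_LATERALITY,false,false
E1122,CM,,NO_LATERALITY,false,false
I252,CM,,NO_LATERALITY,false,false
Z85528,CM,,NO_LATERALITY,false,false
R200,CM,,NO_LATERALITY,false,false
R591,CM,,NO_LATERALITY,false,false
I4510,CM,,NO_LATERALITY,false,false
F329,CM,,NO_LATERALITY,false,false
Z880,CM,,NO_LATERALITY,false,false
Z79899,CM,,NO_LATERALITY,false,false
G40909,CM,,NO_LATERALITY,false,false
I110,CM,,NO_LATERALITY,false,false
E669,CM,,NO_LATERALITY,false,false
G2581,CM,,NO_LATERALITY,false,false
B964,CM,,NO_LATERALITY,false,false
I428,CM,,NO_LATERALITY,false,false
G8918,CM,,NO_LATERALITY,false,false
M109,CM,,NO_LATERALITY,false,false
I69354,CM,,NO_LATERALITY,false,false
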