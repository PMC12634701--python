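# Average-adult sagittal anthropometry, version 1.
# body_height_mm: mid-sagittal vertebral body height.
# disc_height_mm: height of the disc BELOW the level (S1 row: sacro-pelvic offset unused).
# mass_fraction: fraction of total body mass supported as a new increment at this level
#   (T1 lumps head+neck and both upper limbs; trunk slices below). Sum ~0.55 of body mass
#   carried at the lumbosacral junction.
level,body_height_mm,disc_height_mm,mass_fraction
T1,16.0,4.0,0.179
T2,17.0,4.0,0.021
T3,17.5,4.2,0.021
T4,18.0,4.4,0.021
T5,18.5,4.6,0.021
T6,19.0,4.8,0.021
T7,19.5,5.0,0.021
T8,20.0,5.2,0.021
T9,20.5,5.4,0.021
T10,21.5,5.6,0.021
T11,22.5,6.0,0.021
T12,23.5,6.5,0.021
L1,25.0,8.0,0.028
L2,26.0,9.0,0.028
L3,27.0,10.0,0.028
L4,27.0,11.0,0.028
L5,26.0,10.0,0.028
S1,30.0,0.0,0.0
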