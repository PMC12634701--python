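# Default functional-spinal-unit constitutive table, version 1.
# Flexion/extension moment-rotation: M(theta) = kappa * (k0*theta + c*sinh(theta/theta_ref)),
#   M in N*m, theta in degrees. k0 = neutral-zone tangent stiffness (N*m/deg),
#   c (N*m) and theta_ref (deg) shape the stiffening corridor.
# kappa: rib-cage stiffening multiplier (thoracic junctions only).
# shear/axial: linear spring stiffness, N/mm.
# corridor_lo/hi_deg: expected rotation range under a pure 7.5 N*m flexion moment.
# Values are an in-house plausible average-adult parameterization consistent with the
# spread of published cadaveric corridors; absolute outputs that depend on them are
# validated by rank/ratio properties only.
junction,k0,c,theta_ref,kappa,shear,axial,corridor_lo_deg,corridor_hi_deg
T1-T2,0.45,0.50,2.0,1.6,220,1800,2.0,7.0
T2-T3,0.45,0.50,2.0,1.7,220,1800,2.0,7.0
T3-T4,0.45,0.50,2.0,1.8,220,1800,2.0,7.0
T4-T5,0.45,0.50,2.0,1.9,220,1800,2.0,7.0
T5-T6,0.45,0.50,2.0,2.0,220,1800,2.0,7.0
T6-T7,0.45,0.50,2.0,2.0,220,1800,2.0,7.0
T7-T8,0.45,0.50,2.0,2.0,220,1800,2.0,7.0
T8-T9,0.45,0.50,2.0,2.0,220,1800,2.0,7.0
T9-T10,0.45,0.50,2.0,1.9,220,1800,2.0,7.0
T10-T11,0.45,0.50,2.0,1.8,220,1800,2.0,7.5
T11-T12,0.45,0.50,2.0,1.6,220,1800,2.5,8.0
T12-L1,0.40,0.45,2.2,1.3,200,1600,3.0,9.0
L1-L2,0.30,0.40,2.5,1.0,180,1500,4.0,10.0
L2-L3,0.30,0.40,2.5,1.0,180,1500,4.0,10.0
L3-L4,0.30,0.40,2.5,1.0,180,1500,4.0,10.0
L4-L5,0.28,0.38,2.5,1.0,180,1500,4.0,11.0
L5-S1,0.32,0.45,2.5,1.0,200,1600,3.5,10.0
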