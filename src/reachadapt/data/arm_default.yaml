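# Planar arm surrogate parameters (versioned; loaded by reachadapt.arm.default_arm)
# Endpoint frame: origin at movement start, x right, y away from the body.
version: 1
l1: 0.5
l2: 0.5
shoulder: [0.0, -0.55]
# Calibrated jointly (gain_scale, gain_aniso, baseline) so that the
# inverse problem is well conditioned over the 10-170 deg workspace and a
# gradient step with learning rate 2 contracts 20-cm reach errors at
# roughly 60%/trial laterally and 20%/trial in depth (see docs/methods.md).
gain_scale: 0.011
gain_aniso: 0.5
baseline: 6.0
ref_angle: 90.0
ref_radius: 0.20
elbow_sign: 1.0
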