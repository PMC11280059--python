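compartment,volume_L,flow_fraction
lung,0.5,
heart,0.33,0.04
brain,1.45,0.12
muscle,29.0,0.17
adipose,13.5,0.05
skin,3.3,0.05
bone,10.5,0.05
liver,1.8,0.065
kidney,0.31,0.19
gut,1.1,0.14
spleen,0.15,0.03
pancreas,0.1,0.01
rest,3.0,0.085
arterial_blood,1.7,
venous_blood,3.9,
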