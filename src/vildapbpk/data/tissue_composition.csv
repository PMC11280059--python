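tissue,f_water,f_neutral_lipid,f_phospholipid
adipose,0.18,0.79,0.002
bone,0.439,0.074,0.0011
brain,0.77,0.051,0.0565
gut,0.718,0.0487,0.0163
heart,0.758,0.0115,0.0166
kidney,0.783,0.0207,0.0162
liver,0.751,0.0348,0.0252
lung,0.811,0.003,0.009
muscle,0.76,0.0238,0.0072
pancreas,0.664,0.0403,0.009
skin,0.718,0.0284,0.0111
spleen,0.788,0.0201,0.0198
rest,0.76,0.0238,0.0072
plasma,0.945,0.0035,0.00225
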