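{
  "drug_vildagliptin.yaml": "3f6730b0b52ca7fbcedcb2fbf42dd49c4ca34fd989d42b539fba8be10dc93e8d",
  "reference_anatomy.csv": "06059f85ece197d60fc90cafb1c6e3ad13b7a6134e1d1b3235a8b6bb574bfd30",
  "table1_pk_ratios.csv": "791621e51fd3de3882e701202ad1e5610f6955667682fea287a34dffe08b1100",
  "table2_afe.csv": "a0a12792002f8fa7b871444bc8de70394d347440ea543f94e63c79dc21803db5",
  "table3_studies.csv": "80ee6e6a3d50e42e67ed5606e055bc61c1287a778fbcef7e08daf6848327b8a8",
  "tissue_composition.csv": "fbb84c9c1c0975661472e577f2568ff848053a7fbc549021a4376aa5edf99377"
}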