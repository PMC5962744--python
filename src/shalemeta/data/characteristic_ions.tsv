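#class_name	characteristic_ions
alcohol	45;59;73;87
aldehyde	44;58;72
aliphatic	43;57;71;85;99
aromatic	65;77;78;79
carboxylic_acid	43;45;57;59;60;71;73;85;87
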