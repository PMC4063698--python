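condition,wandering_h,pupariation_h,wandering_ci_lo,wandering_ci_hi,pupariation_ci_lo,pupariation_ci_hi
SAM_25C,46,49,,,,
SAM_18C,96,101,,,,
SAM_29C,48,52,,,,
P0206>PTEN,73,80,,,,
phm>InR,32,36,,,,
>PTEN,48,53,,,,
>InR,48,51,,,,
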