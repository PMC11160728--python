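protein,stage,nuclear_relative_pct,nuclear_copies,bound_frac_spotbleach,bound_frac_frap,residence_time_s,longterm_frac
SMC4,early_G1,104,178000,0.21,0.19,28,0.13
NCAPH,early_G1,103,127000,0.15,0.11,45,0.09
NCAPH2,early_G1,99,25400,0.22,,,
CTCF,early_G1,102,125500,0.5,0.62,125,0.32
RAD21,early_G1,63,151000,0.41,0.53,155,0.28
STAG1,early_G1,100,53500,0.37,0.62,244,0.27
STAG2,early_G1,56,102000,0.37,0.47,108,0.07
SMC4,G1,100,174000,0.1,,,
NCAPH,G1,100,125000,0.09,,,
NCAPH2,G1,100,25600,0.02,,,
CTCF,G1,100,124000,0.72,0.72,139,0.488
RAD21,G1,100,238000,0.59,0.77,172,0.277
STAG1,G1,100,53500,0.59,0.76,276,0.39
STAG2,G1,100,183000,0.5,0.71,126,0.107
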