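chemical_id,name,value,kind,source
NP,4-Nonylphenol,1.00,chronic,aquatic-life benchmark compilation
ANT,Anthracene,0.01,chronic,aquatic-life benchmark compilation
BAP,Benzo[a]pyrene,0.01,chronic,aquatic-life benchmark compilation
DEHP,Bis(2-ethylhexyl) phthalate,0.30,chronic,aquatic-life benchmark compilation
DCVP,Dichlorvos,0.01,chronic,aquatic-life benchmark compilation
FLU,Fluoranthene,0.04,chronic,aquatic-life benchmark compilation
PYR,Pyrene,0.03,chronic,aquatic-life benchmark compilation
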