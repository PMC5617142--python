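chemical_id,eeq_factor,source
E2,1.0,synthetic example factor table (order-of-magnitude literature potencies; not an authoritative compilation)
E1,0.38,synthetic example factor table
OP,0.001,synthetic example factor table
NP,0.0009,synthetic example factor table
BPA,0.0001,synthetic example factor table
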