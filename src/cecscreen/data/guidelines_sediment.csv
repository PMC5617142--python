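chemical_id,name,tec,mec,pec,source
DCBZ,"1,4-Dichlorobenzene",31,60.5,90,state sediment quality guidelines
MNAP2,2-Methylnaphthalene,20.2,111,201,state sediment quality guidelines
ANT,Anthracene,57.2,451,845,state sediment quality guidelines
BAP,Benzo[a]pyrene,150,800,1450,state sediment quality guidelines
FLU,Fluoranthene,423,1327,2230,state sediment quality guidelines
NAP,Naphthalene,176,369,561,state sediment quality guidelines
PHENA,Phenanthrene,204,687,1170,state sediment quality guidelines
PHEOL,Phenol,4200,8100,12000,state sediment quality guidelines
PYR,Pyrene,195,858,1520,state sediment quality guidelines
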