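matrix,chemical_id,name,chemical_class,log_kow,reporting_limit,n_analyzed,median,maximum,detection_frequency
water,CHOL,Cholesterol,sterol,7.69,0.20,285,1.80,72.2,100
water,ISO,Isophorone,other,1.7,0.05,291,0.0068,0.0548,72
water,METF,Metformin,pharmaceutical,-0.88,0.013,288,0.0465,33.6,71
water,ATZ,Atrazine,pesticide,2.61,0.019,292,0.0184,0.814,70
water,DEET,"N,N-Diethyl-m-toluamide",insect repellant,2.18,0.04,291,0.021,5.07,68
water,METCH,Metolachlor,pesticide,3.13,0.04,291,0.0136,1.53,62
water,BSS,beta-Sitosterol,sterol,8.25,4.8,291,0.42,7.77,61
water,CMZ,Carbamazepine,pharmaceutical,2.45,0.0041,292,0.00128,0.333,52
water,TBEP,tris(2-butoxyethyl) phosphate,flame retardant,2.75,0.64,291,0.105,38.7,52
water,LID,Lidocaine,pharmaceutical,1.44,0.015,292,0.00015,2.06,50
water,MBTZ,methyl-1H-benzotriazole,industrial,1.44,0.141,292,0.004,8.06,50
water,DESVEN,Desvenlafaxine,pharmaceutical,,0.00749,292,,1.24,48
water,METHO,Methocarbamol,pharmaceutical,0.61,0.00872,292,,0.592,47
water,TRAM,Tramadol,pharmaceutical,2.38,0.0151,292,,0.863,46
water,COT,Cotinine,other,0.07,0.00637,292,,0.121,45
water,HHCB,hexahydrohexamethyl cyclopentabenzopyran,fragrance,5.9,0.04,291,,2.18,44
water,IND,Indole,fecal indicator,2.14,0.04,289,,0.0284,44
water,FEXO,Fexofenadine,pharmaceutical,3.88,0.0199,292,,3.62,43
water,ANQN,"9,10-Anthraquinone",industrial,3.39,0.04,291,,0.402,42
water,VEN,Venlafaxine,pharmaceutical,2.51,0.00448,292,,0.319,42
water,CAFF,Caffeine,other,-0.07,0.0907,292,,6.61,40
water,TDIP,tris(dichloroisopropyl) phosphate,flame retardant,3.65,0.32,291,,0.44,37
water,NIC,Nicotine,other,1.17,0.0578,292,,0.492,37
water,ACYC,Acyclovir,pharmaceutical,-1.56,0.0222,292,,1.11,36
water,FLU,Fluoranthene,PAH,5.16,0.02,291,,0.671,36
water,SMX,Sulfamethoxazole,pharmaceutical,0.89,0.0261,292,,1.39,36
water,TRIAM,Triamterene,pharmaceutical,0.98,0.00525,292,,0.382,36
water,PYR,Pyrene,PAH,4.88,0.02,291,,0.512,35
water,ATEN,Atenolol,pharmaceutical,0.16,0.0133,292,,1.70,34
water,COP,3beta-Coprostanol,sterol,8.22,1.6,291,,14.4,34
water,MPB,Meprobamate,pharmaceutical,0.7,0.086,292,,0.114,32
water,METP,Metoprolol,pharmaceutical,1.88,0.0275,292,,0.415,30
sediment,IND,Indole,fecal indicator,2.14,50,76,130,1240,100
sediment,MIND,3-Methyl-1H-indole,fecal indicator,2.6,33,76,10.7,574,91
sediment,FLU,Fluoranthene,PAH,5.16,41.5,76,192,20800,87
sediment,PYR,Pyrene,PAH,4.88,41.5,76,165,18300,87
sediment,BAP,Benzo[a]pyrene,PAH,6.13,41.5,76,65.3,1790,86
sediment,DMNAP,"2,6-Dimethylnaphthalene",PAH,4.31,33,76,25.5,338,84
sediment,CARB,Carbazole,other,3.72,34.5,76,15.4,678,80
sediment,ANT,Anthracene,PAH,4.45,40,76,15.5,918,76
sediment,PHENA,Phenanthrene,PAH,4.46,37.5,76,112.5,2840,74
sediment,ANQN,"9,10-Anthraquinone",industrial,3.39,33,71,46.1,899,73
sediment,MP,p-Cresol,phenolic,1.94,165,76,73.2,9330,72
sediment,E1,Estrone,hormone,3.13,0.053,76,0.32,10.93,68
sediment,A4,"4-Androstene-3,17-dione",hormone,2.75,0.053,76,0.171,2.85,67
sediment,CHOL,Cholesterol,sterol,7.69,165,76,586,5400,54
sediment,MNAP1,1-Methylnaphthalene,PAH,3.87,33,76,1.045,197,50
sediment,MNAP2,2-Methylnaphthalene,PAH,3.86,33,76,,406,49
sediment,HHCB,hexahydrohexamethyl cyclopentabenzopyran,fragrance,5.9,33,76,,660,46
sediment,BSS,beta-Sitosterol,sterol,8.25,330,76,,15200,43
sediment,NAP,Naphthalene,PAH,3.3,33,76,,1720,43
sediment,BSM,beta-Stigmastanol,sterol,8.63,330,76,,5250,42
sediment,ISO,Isophorone,other,1.7,33,76,,46.2,41
sediment,OP,4-tert-Octylphenol,alkylphenol,5.28,33,75,,169,37
sediment,BPA,Bisphenol A,plasticizer,3.32,33,76,,380,37
sediment,E2,17beta-Estradiol,hormone,4.01,0.053,74,,5.85,36
sediment,AND,cis-Androsterone,hormone,3.69,0.053,76,,6.91,36
sediment,DPHD,Diphenhydramine,pharmaceutical,3.27,2.7,77,,1.75,32
sediment,DCBZ,"1,4-Dichlorobenzene",other,3.44,33,76,,1160,30
sediment,AHTN,acetyl hexamethyl tetrahydronaphthalene,fragrance,5.7,33,76,,104,30
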