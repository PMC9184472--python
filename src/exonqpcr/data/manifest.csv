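assay_id,gene,exon_region_index,design_suffix,best_coverage
AR7DTG3,FDXR,1,custom,False
Hs00244586_m1,FDXR,2,m1,True
Hs01031621_g1,FDXR,3,g1,False
Hs01031617_m1,FDXR,4,m1,False
ARCE69Z,FDXR,5,custom,False
Hs00244590_m1,FDXR,6,m1,False
AREPVEV,FDXR,7,custom,False
AR7DTRF,FDXR,8,custom,False
ARDJZUX,FDXR,9,custom,False
PLACEHOLDER_FDXR_1,FDXR,10,custom,False
PLACEHOLDER_FDXR_2,FDXR,11,custom,False
PLACEHOLDER_FDXR_3,FDXR,12,custom,False
PLACEHOLDER_FDXR_4,FDXR,13,custom,False
PLACEHOLDER_FDXR_5,FDXR,14,custom,False
PLACEHOLDER_FDXR_6,FDXR,15,custom,False
PLACEHOLDER_FDXR_7,FDXR,16,custom,False
AR47X6H,DDB2,1,custom,False
Hs03044951_m1,DDB2,2,m1,False
AR9HMCD,DDB2,3,custom,False
Hs01585060_m1,DDB2,4,m1,False
Hs00172068_m1,DDB2,5,m1,True
PLACEHOLDER_DDB2_1,DDB2,6,custom,False
PLACEHOLDER_DDB2_2,DDB2,7,custom,False
PLACEHOLDER_DDB2_3,DDB2,8,custom,False
PLACEHOLDER_DDB2_4,DDB2,9,custom,False
PLACEHOLDER_DDB2_5,DDB2,10,custom,False
PLACEHOLDER_DDB2_6,DDB2,11,custom,False
Hs00902255_m1,WNT3,1,m1,False
Hs00229135_m1,WNT3,2,m1,False
PLACEHOLDER_WNT3_1,WNT3,3,custom,False
Hs00902257_m1,WNT3,4,m1,False
Hs00902258_m1,WNT3,5,m1,True
ARZTGFR,POU2AF1,1,custom,False
Hs00174811_m1,POU2AF1,2,m1,False
ARYMMVU,POU2AF1,3,custom,False
Hs01573369_m1,POU2AF1,4,m1,True
AR324KK,POU2AF1,5,custom,False
PLACEHOLDER_POU2AF1_1,POU2AF1,6,custom,False
PLACEHOLDER_POU2AF1_2,POU2AF1,7,custom,False
Hs01573370_g1,POU2AF1,8,g1,False
Hs01573371_m1,POU2AF1,9,m1,False
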