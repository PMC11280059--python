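route,population,stage,dose_mg,day,cmax_obs,cmax_pred,cmax_r,auc_obs,auc_pred,auc_r,cl_obs,cl_pred,cl_r,ref
oral,healthy,,25,1,140,127,0.90,566,507,0.89,44,49,1.11,B35
oral,healthy,,25,13,138,125,0.90,541,507,0.93,46,49,1.06,B35
oral,healthy,,25,,112,127,1.13,475,499,1.05,50,50,1.00,B38
oral,healthy,,50,1,294,254,0.86,1269,980,0.77,39,50,1.28,B35
oral,healthy,,50,13,339,250,0.73,1241,962,0.77,40,50,1.25,B35
oral,healthy,,50,,212,242,1.14,1164,989,0.84,42.9,50,1.16,B38
oral,healthy,,50,,191,243,1.27,1097,1019,0.92,45,49,1.08,B30
oral,healthy,,100,1,654,509,0.77,2799,2010,0.71,35,49.7,1.42,B35
oral,healthy,,100,13,610,509,0.83,2667,1987,0.74,37,50,1.35,B35
oral,healthy,,100,,446,484,1.08,2670,1871,0.70,37,53,1.43,B38
oral,healthy,,100,,350,410,1.17,1630,1767,1.08,60,56,0.93,B37
oral,healthy,,200,1,1247,1019,0.81,5776,4073,0.70,34.6,49,1.41,B35
oral,healthy,,200,13,1173,1001,0.85,5760,4125,0.71,34,48,1.41,B35
oral,healthy,,200,,902,953,1.05,5314,3525,0.66,37.6,56,1.48,B38
iv,healthy,,25,,476,337,0.70,660,479,0.73,51,52.1,1.02,B30
oral,ckd,mild,50,,224,277,1.23,976,1204,1.23,51,40,0.78,B36
oral,ckd,moderate,50,,310,342,1.10,1792,2107,1.17,27.8,23.6,0.84,B36
oral,ckd,severe,50,,353,406,1.15,2366,3519,1.48,21,14.2,0.67,B36
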