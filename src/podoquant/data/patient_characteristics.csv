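sample_id,group,proteinuria_value,proteinuria_unit,proteinuria_censored,creatinine_mg_dl,nephrotic_syndrome
MC 1,MC,15.7,g/g creatinine,False,2.12,Yes
MC 2,MC,10,g/g creatinine,False,0.72,Yes
MC 3,MC,5,g/l,False,0.59,Yes
MC 4,MC,0.5,g/dl,True,3.5,Yes
MC 5,MC,9.7,g/24 h,False,1.2,Yes
Prim FSGS 1,Prim FSGS,5,g/24 h,False,1.51,n.d
Prim FSGS 2,Prim FSGS,9,g/24 h,False,1.28,Yes
Prim FSGS 3,Prim FSGS,6,g/24 h,False,1.11,Yes
Prim FSGS 4,Prim FSGS,8.4,g/g creatinine,False,0.7,Yes
Prim FSGS 5,Prim FSGS,6.08,g/24 h,False,0.7,Yes
Sec FSGS 1,Sec FSGS,2.3,g/24 h,False,1.2,No
Sec FSGS 2,Sec FSGS,10.8,g/g creatinine,False,4.14,No
Sec FSGS 3,Sec FSGS,4,g/24 h,False,2.3,No
Sec FSGS 4,Sec FSGS,8,g/24 h,True,4.67,No
Sec FSGS 5,Sec FSGS,4.8,g/24 h,False,3.19,No
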