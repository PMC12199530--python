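study,kind,group,role,n
DOCA-salt,rodent,control,control,5
DOCA-salt,rodent,DOCA/UNX,treated,5
NTS,rodent,control,control,4
NTS,rodent,NTS,treated,7
PAN,rodent,control,control,5
PAN,rodent,PAN,treated,7
human cohort 1,human,control,control,5
human cohort 1,human,MCD,treated,5
human cohort 1,human,Prim FSGS,treated,5
human cohort 1,human,Sec FSGS,treated,5
human cohort 2,human,MCD,treated,8
human cohort 2,human,FSGS,treated,4
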