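subject_id,label,delta_1,delta_2,delta_3,delta_4,delta_5
PB-1,PB,11,23,11,6,2
PB-2,PB,2,28,17,7,3
PB-3,PB,11,29,13,5,2
PB-4,PB,9,30,13,7,3
PB-5,PB,14,27,14,4,2
PB-6,PB,8,25,13,5,2
PB-7,PB,0,28,14,6,3
PB-8,PB,21,25,16,8,3
PB-9,PB,0,30,15,7,3
PB-10,PB,3,23,9,5,2
nPB-1,nPB,7,26,16,6,3
nPB-2,nPB,7,29,15,8,2
nPB-3,nPB,8,28,16,9,4
nPB-4,nPB,2,24,14,7,3
nPB-5,nPB,4,28,17,10,5
nPB-6,nPB,0,30,17,7,5
nPB-7,nPB,15,26,15,6,2
nPB-8,nPB,8,27,15,7,3
nPB-9,nPB,9,26,16,8,4
nPB-10,nPB,2,31,17,8,3
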