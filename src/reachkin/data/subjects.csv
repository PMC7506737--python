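id,sex,age_years,months_since_stroke,type,territory,affected_side,fma_total,fma_arm,fma_wrist,fma_hand
S01,M,72,73,Isch,PCA,L,35,22,6,10
S02,M,73,30,Isch,MCA,R,33,22,7,9
S03,M,62,181,Hem,(BG),R,33,26,7,5
S04,F,61,70,Isch,ACA,L,40,22,6,13
S05,M,57,45,Isch,ACA,L,46,31,8,11
S06,F,70,21,Isch,PCA,R,34,22,5,9
S07,F,70,33,Isch,MCA,L,34,22,6,11
S08,M,59,9,Isch,MCA,R,32,16,4,11
S09,F,42,20,Isch,MCA/ICA,R,32,24,3,6
S10,M,42,13,Isch,MCA/PCA,L,28,25,6,2
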