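subject_id,group,Numero Risposte,G,D,Dd,DG,F,F+,F-,M,FM,m,CF,Fcho,CHO,BAN,ORIG,ORIG+,A,Ad,U,(u),Ud,Obj,Cibo,Nat,Bot,Anat,Fumo,Cartoon,Art,IR,TRI I,TRI II,Perseverazioni,Inadeguatezza,Insicurezza,Stereotipie,Rifiuti,Confabulazione,Astrazione,Contaminazione,Diff. Denominazione,Autoriferimento,Devitalizzazione,Sensazione
Demenza 1,AD,8,8,0,0,0,8,5,3,0,0,0,0,0,0,0,0,0,6,0,0,0,0,2,0,0,0,0,0,1,0,0,3,3,0,0,0,0,1,0,0,0,0,0,0,0
Demenza 2,AD,7,2,5,0,0,5,1,4,1,0,0,0,1,0,2,0,0,5,0,1,0,0,0,0,0,1,0,0,0,0,4,1,3,0,1,0,0,1,1,0,0,0,0,0,0
Demenza 3,AD,10,4,3,0,3,8,3,5,0,0,1,1,0,0,1,0,0,3,0,0,0,2,4,1,0,0,0,0,0,0,2,3,2,1,0,1,0,1,0,0,0,0,0,0,0
Demenza 4,AD,15,7,8,0,0,14,12,2,1,0,0,0,0,0,4,1,1,9,0,3,0,0,2,0,1,0,0,0,0,0,5,1,3,1,0,1,1,1,0,0,0,0,0,0,0
Demenza 5,AD,9,1,7,1,0,9,7,2,0,0,0,0,0,0,1,0,0,5,2,0,0,0,0,0,0,2,0,0,0,0,2,3,3,1,1,1,0,1,1,0,0,0,0,0,0
Demenza 6,AD,13,3,9,0,1,11,8,3,1,0,0,0,1,0,3,1,1,7,1,2,0,0,0,1,0,2,0,0,0,0,4,1,2,0,1,1,0,1,0,0,0,0,1,0,0
Demenza 7,AD,8,2,6,0,0,7,7,0,1,0,0,0,0,0,2,0,0,3,0,2,0,3,0,0,0,0,0,0,0,0,4,1,3,0,1,1,0,0,0,0,0,0,1,0,0
Demenza 8,AD,7,5,2,0,0,4,2,2,3,0,0,0,0,0,1,0,0,0,0,5,0,0,0,0,0,2,0,0,0,0,2,1,3,1,0,0,0,1,1,1,0,1,0,0,1
INPH 1 pr,INPH,10,7,3,0,0,6,5,1,0,4,0,0,0,0,1,0,0,9,0,0,0,0,1,0,0,0,0,0,0,0,2,3,1,0,0,0,0,0,0,0,0,0,0,0,0
INPH 2 pr,INPH,13,5,8,0,0,13,7,6,0,0,0,0,0,0,4,0,0,7,4,0,0,0,1,0,0,0,1,0,0,0,6,3,3,0,0,0,0,0,1,0,0,0,0,0,0
INPH 3 pr,INPH,13,6,7,0,0,13,10,3,0,0,0,0,0,0,4,0,0,10,0,0,0,0,0,0,0,3,0,0,0,0,5,3,3,1,0,0,0,1,0,0,0,0,0,0,0
INPH 4 pr,INPH,16,13,3,0,0,15,7,8,1,0,0,0,0,0,4,0,0,6,1,2,0,1,3,1,0,0,1,0,1,0,6,1,3,0,0,0,0,0,0,0,0,0,0,1,0
INPH 5 pr,INPH,7,7,0,0,0,7,7,0,0,0,0,0,0,0,2,0,0,7,0,0,0,0,0,0,0,0,0,0,0,0,2,3,3,1,0,0,0,0,0,0,0,0,0,0,0
INPH 6 pr,INPH,12,7,5,0,0,7,3,4,1,3,0,0,0,1,3,0,0,6,0,0,1,1,0,0,1,0,3,1,0,0,4,1,1,0,0,0,0,0,0,0,0,0,0,0,1
INPH 7 pr,INPH,4,3,1,0,0,2,2,0,1,1,0,0,0,0,3,0,0,3,0,1,0,0,0,0,0,0,0,0,0,0,6,1,1,0,0,0,0,1,0,0,0,0,0,0,0
INPH 8 pr,INPH,11,6,5,0,0,8,4,4,1,1,0,0,0,0,1,0,0,6,1,1,0,0,2,0,0,0,0,0,0,1,2,1,1,0,0,0,0,1,0,0,0,0,0,0,0
INPH 9 pr,INPH,4,3,1,0,0,2,2,0,1,1,0,0,0,0,3,0,0,3,0,1,0,0,0,0,0,0,0,0,0,0,6,1,1,0,0,0,0,1,0,0,0,0,0,0,0
INPH 10 pr,INPH,11,7,4,0,0,7,4,3,1,3,0,0,0,0,2,0,0,7,0,2,0,0,0,0,0,1,1,0,0,0,4,1,1,0,0,0,0,1,0,0,0,0,0,1,0
INPH 11 pr,INPH,18,7,10,1,0,16,11,5,1,1,0,0,0,0,1,0,0,9,0,4,1,0,3,0,0,0,0,0,0,1,2,1,1,1,0,0,0,0,0,0,1,0,0,0,0
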