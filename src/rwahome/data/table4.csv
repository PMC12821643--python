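patient_id,rbdsq,rwa_pct,group
Pt. 1,5,39.1,C
Pt. 2,6,29.7,C
Pt. 3,11,29.1,C
Pt. 4,10,14.0,C
Pt. 5,8,12.8,C
Pt. 6,6,1.2,C
Pt. 7,11,14.1,C
Pt. 8,8,3.3,C
Pt. 9,5,21.1,C
Pt. 10,12,21.7,C
Pt. 11,10,24.1,C
Pt. 12,6,2.3,C
Pt. 13,6,4.1,C
Pt. 14,5,17.4,C
Pt. 15,8,32.1,C
Pt. 16,3,7.2,B
Pt. 17,3,18.3,B
Pt. 18,4,84.3,B
Pt. 19,2,12.2,B
Pt. 20,3,22.9,B
Pt. 21,3,51.4,B
Pt. 22,2,4.4,B
Pt. 23,4,26.0,B
Pt. 24,3,17.5,B
Pt. 25,4,25.7,B
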