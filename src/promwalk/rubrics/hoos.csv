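# Instrument rubric, one row per response option.
#   item_id  - short key identifying the question
#   domain   - scoring domain the item belongs to
#   retained - 'true' if the item contributes to the total (the mHHS
#              public-transport item is kept for validation but excluded)
#   code     - integer response code as recorded on the form (0 = best)
#   points   - points awarded for that response
item_id,domain,retained,code,points
P1,pain,true,0,0
P1,pain,true,1,1
P1,pain,true,2,2
P1,pain,true,3,3
P1,pain,true,4,4
P2,pain,true,0,0
P2,pain,true,1,1
P2,pain,true,2,2
P2,pain,true,3,3
P2,pain,true,4,4
P3,pain,true,0,0
P3,pain,true,1,1
P3,pain,true,2,2
P3,pain,true,3,3
P3,pain,true,4,4
P4,pain,true,0,0
P4,pain,true,1,1
P4,pain,true,2,2
P4,pain,true,3,3
P4,pain,true,4,4
P5,pain,true,0,0
P5,pain,true,1,1
P5,pain,true,2,2
P5,pain,true,3,3
P5,pain,true,4,4
P6,pain,true,0,0
P6,pain,true,1,1
P6,pain,true,2,2
P6,pain,true,3,3
P6,pain,true,4,4
P7,pain,true,0,0
P7,pain,true,1,1
P7,pain,true,2,2
P7,pain,true,3,3
P7,pain,true,4,4
P8,pain,true,0,0
P8,pain,true,1,1
P8,pain,true,2,2
P8,pain,true,3,3
P8,pain,true,4,4
P9,pain,true,0,0
P9,pain,true,1,1
P9,pain,true,2,2
P9,pain,true,3,3
P9,pain,true,4,4
P10,pain,true,0,0
P10,pain,true,1,1
P10,pain,true,2,2
P10,pain,true,3,3
P10,pain,true,4,4
S1,symptoms,true,0,0
S1,symptoms,true,1,1
S1,symptoms,true,2,2
S1,symptoms,true,3,3
S1,symptoms,true,4,4
S2,symptoms,true,0,0
S2,symptoms,true,1,1
S2,symptoms,true,2,2
S2,symptoms,true,3,3
S2,symptoms,true,4,4
S3,symptoms,true,0,0
S3,symptoms,true,1,1
S3,symptoms,true,2,2
S3,symptoms,true,3,3
S3,symptoms,true,4,4
S4,symptoms,true,0,0
S4,symptoms,true,1,1
S4,symptoms,true,2,2
S4,symptoms,true,3,3
S4,symptoms,true,4,4
S5,symptoms,true,0,0
S5,symptoms,true,1,1
S5,symptoms,true,2,2
S5,symptoms,true,3,3
S5,symptoms,true,4,4
A1,activities,true,0,0
A1,activities,true,1,1
A1,activities,true,2,2
A1,activities,true,3,3
A1,activities,true,4,4
A2,activities,true,0,0
A2,activities,true,1,1
A2,activities,true,2,2
A2,activities,true,3,3
A2,activities,true,4,4
A3,activities,true,0,0
A3,activities,true,1,1
A3,activities,true,2,2
A3,activities,true,3,3
A3,activities,true,4,4
A4,activities,true,0,0
A4,activities,true,1,1
A4,activities,true,2,2
A4,activities,true,3,3
A4,activities,true,4,4
A5,activities,true,0,0
A5,activities,true,1,1
A5,activities,true,2,2
A5,activities,true,3,3
A5,activities,true,4,4
A6,activities,true,0,0
A6,activities,true,1,1
A6,activities,true,2,2
A6,activities,true,3,3
A6,activities,true,4,4
A7,activities,true,0,0
A7,activities,true,1,1
A7,activities,true,2,2
A7,activities,true,3,3
A7,activities,true,4,4
A8,activities,true,0,0
A8,activities,true,1,1
A8,activities,true,2,2
A8,activities,true,3,3
A8,activities,true,4,4
A9,activities,true,0,0
A9,activities,true,1,1
A9,activities,true,2,2
A9,activities,true,3,3
A9,activities,true,4,4
A10,activities,true,0,0
A10,activities,true,1,1
A10,activities,true,2,2
A10,activities,true,3,3
A10,activities,true,4,4
A11,activities,true,0,0
A11,activities,true,1,1
A11,activities,true,2,2
A11,activities,true,3,3
A11,activities,true,4,4
A12,activities,true,0,0
A12,activities,true,1,1
A12,activities,true,2,2
A12,activities,true,3,3
A12,activities,true,4,4
A13,activities,true,0,0
A13,activities,true,1,1
A13,activities,true,2,2
A13,activities,true,3,3
A13,activities,true,4,4
A14,activities,true,0,0
A14,activities,true,1,1
A14,activities,true,2,2
A14,activities,true,3,3
A14,activities,true,4,4
A15,activities,true,0,0
A15,activities,true,1,1
A15,activities,true,2,2
A15,activities,true,3,3
A15,activities,true,4,4
A16,activities,true,0,0
A16,activities,true,1,1
A16,activities,true,2,2
A16,activities,true,3,3
A16,activities,true,4,4
A17,activities,true,0,0
A17,activities,true,1,1
A17,activities,true,2,2
A17,activities,true,3,3
A17,activities,true,4,4
SP1,sport,true,0,0
SP1,sport,true,1,1
SP1,sport,true,2,2
SP1,sport,true,3,3
SP1,sport,true,4,4
SP2,sport,true,0,0
SP2,sport,true,1,1
SP2,sport,true,2,2
SP2,sport,true,3,3
SP2,sport,true,4,4
SP3,sport,true,0,0
SP3,sport,true,1,1
SP3,sport,true,2,2
SP3,sport,true,3,3
SP3,sport,true,4,4
SP4,sport,true,0,0
SP4,sport,true,1,1
SP4,sport,true,2,2
SP4,sport,true,3,3
SP4,sport,true,4,4
Q1,qol,true,0,0
Q1,qol,true,1,1
Q1,qol,true,2,2
Q1,qol,true,3,3
Q1,qol,true,4,4
Q2,qol,true,0,0
Q2,qol,true,1,1
Q2,qol,true,2,2
Q2,qol,true,3,3
Q2,qol,true,4,4
Q3,qol,true,0,0
Q3,qol,true,1,1
Q3,qol,true,2,2
Q3,qol,true,3,3
Q3,qol,true,4,4
Q4,qol,true,0,0
Q4,qol,true,1,1
Q4,qol,true,2,2
Q4,qol,true,3,3
Q4,qol,true,4,4
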