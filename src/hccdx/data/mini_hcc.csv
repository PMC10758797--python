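Gender,Symptoms,Alcohol,Hepatitis B Surface Antigen,Hepatitis B E Antigen,Hepatitis B Core Antibody,Hepatitis C Virus Antibody,Cirrhosis,Endemic Countries,Smoking,Diabetes,Obesity,Class
1,0,0,0,0,0,0,1,0,1,0,0,0
0,1,1,0,0,1,0,1,0,1,1,0,1
1,0,1,0,0,?,0,1,1,1,0,0,0
0,1,1,0,0,?,0,1,0,0,1,?,0
0,1,0,0,0,1,1,1,0,0,1,0,0
1,0,1,0,0,1,0,1,0,?,1,0,0
0,1,0,0,0,0,0,1,1,0,1,0,1
1,1,1,0,0,0,?,1,0,1,1,1,1
1,0,0,0,0,0,0,1,0,1,0,0,1
1,0,1,0,0,0,0,0,0,?,0,1,1
0,1,0,0,0,1,1,0,0,?,1,0,1
1,1,1,0,0,0,0,1,?,?,0,0,1
1,?,1,0,0,1,0,1,1,1,1,0,1
1,1,1,0,0,0,0,1,0,0,1,1,1
1,1,1,0,0,0,0,1,?,?,0,0,0
1,1,1,0,0,1,0,1,1,1,0,?,0
1,?,0,0,0,1,0,1,1,?,0,0,0
0,0,0,?,0,0,0,1,0,1,0,1,0
1,?,0,0,0,?,0,1,0,?,0,0,0
1,1,0,0,?,0,0,1,?,?,0,0,1
0,1,1,0,0,0,0,1,?,0,0,0,0
1,0,1,0,0,?,?,0,?,0,1,0,1
1,0,1,0,0,0,0,1,0,?,1,0,0
1,0,1,1,?,1,0,1,?,1,0,0,1
0,0,0,0,0,?,0,0,?,0,0,0,1
0,1,0,0,0,0,0,1,0,1,0,0,1
0,0,0,0,?,0,0,1,0,0,0,0,0
1,1,1,0,0,0,0,1,0,1,1,0,1
1,0,0,0,0,0,0,0,0,0,1,0,1
1,?,0,1,0,1,0,1,0,1,0,1,0
1,1,1,0,0,0,0,1,0,0,0,0,0
0,1,1,0,0,0,0,1,0,?,1,0,0
0,0,1,0,?,1,0,1,0,1,0,0,1
0,0,0,0,0,?,0,1,0,?,1,0,1
1,?,0,0,?,0,0,1,?,0,1,0,1
1,1,0,0,?,0,0,1,0,1,0,0,0
1,1,1,0,0,0,0,1,0,0,0,0,1
1,0,1,?,?,0,0,1,0,1,1,0,0
1,?,0,0,0,0,0,1,0,0,0,0,1
1,1,0,0,0,0,0,1,?,1,1,0,1
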