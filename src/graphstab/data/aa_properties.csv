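aa,hydropathy,volume,polarity,charge,mw
A,1.8,88.6,8.1,0,89.09
R,-4.5,173.4,10.5,1,174.20
N,-3.5,114.1,11.6,0,132.12
D,-3.5,111.1,13.0,-1,133.10
C,2.5,108.5,5.5,0,121.16
Q,-3.5,143.8,10.5,0,146.15
E,-3.5,138.4,12.3,-1,147.13
G,-0.4,60.1,9.0,0,75.07
H,-3.2,153.2,10.4,0,155.15
I,4.5,166.7,5.2,0,131.17
L,3.8,166.7,4.9,0,131.17
K,-3.9,168.6,11.3,1,146.19
M,1.9,162.9,5.7,0,149.21
F,2.8,189.9,5.2,0,165.19
P,-1.6,112.7,8.0,0,115.13
S,-0.8,89.0,9.2,0,105.09
T,-0.7,116.1,8.6,0,119.12
W,-0.9,227.8,5.4,0,204.23
Y,-1.3,193.6,6.2,0,181.19
V,4.2,140.0,5.9,0,117.15
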