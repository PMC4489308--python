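# Cromer-Mann four-Gaussian form-factor coefficients, neutral atoms.
# Transcribed from the International Tables for Crystallography, Vol. C,
# Table 6.1.1.4: f(q) = sum_k a_k exp(-b_k (q/4pi)^2) + c
# columns: element a1 a2 a3 a4 b1 b2 b3 b4 c
H   0.489918  0.262003  0.196767  0.049879  20.6593   7.74039  49.5519    2.20159   0.001305
C   2.31000   1.02000   1.58860   0.865000  20.8439  10.2075    0.568700 51.6512    0.215600
N  12.2126    3.13220   2.01250   1.16630    0.005700  9.89330 28.9975    0.582600 -11.529
O   3.04850   2.28680   1.54630   0.867000  13.2771   5.70110   0.323900 32.9089    0.250800
F   3.53920   2.64120   1.51700   1.02430   10.2825   4.29440   0.261500 26.1476    0.277600
NA  4.76260   3.17360   1.26740   1.11280    3.28500   8.84220   0.313600 129.424    0.676000
MG  5.42040   2.17350   1.22690   2.30730    2.82750  79.2611    0.380800  7.19370   0.858400
P   6.43450   4.17910   1.78000   1.49080    1.90670  27.1570    0.526000 68.1645    1.11490
S   6.90530   5.20340   1.43790   1.58630    1.46790  22.2151    0.253600 56.1720    0.866900
CL 11.4604    7.19640   6.25560   1.64550    0.010400  1.16620  18.5194   47.7784   -9.5574
K   8.21860   7.43980   1.05190   0.865900  12.7949   0.774800 213.187   41.6841    1.42280
CA  8.62660   7.38730   1.58990   1.02110   10.4421   0.659900  85.7484  178.437    1.37510
MN 11.2819    7.35730   3.01930   2.24410    5.34090   0.343200  17.8674   83.7543   1.08960
FE 11.7695    7.35730   3.52220   2.30450    4.76110   0.307200  15.3535   76.8805   1.03690
CU 13.3380    7.16760   5.61580   1.67350    3.58280   0.247000  11.3966   64.8126   1.19100
ZN 14.0743    7.03180   5.16520   2.41000    3.26550   0.233300  10.3163   58.7097   1.30410
SE 17.0006    5.81960   3.97310   4.35430    2.40980   0.272600  15.2372   43.8163   2.84090
BR 17.1789    5.23580   5.63770   3.98510    2.17230  16.5796    0.260900  41.4328   2.95570
I  20.1472   18.9949    7.51380   2.27350    4.34700   0.381400  27.7660   66.8776   4.07120
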