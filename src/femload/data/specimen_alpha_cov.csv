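# Published load-magnitude scaling factors alpha_1..alpha_4 (unit loads at
# -20/20/60/100 deg, 1000 N resultants) and coefficient of variation (%) of
# the tissue stimulus before (uniform scaling) and after optimisation, for
# ten proximal femoral specimens. Versioned text fixture; v1.
specimen,alpha_1,alpha_2,alpha_3,alpha_4,cov_init,cov_opt
1,1.25,3.32,1.39,0.65,203.83,137.55
2,1.02,2.47,0.12,0.97,403.04,146.89
3,0.97,3.92,0.22,0.08,1515.66,135.75
4,0.45,3.61,1.09,0.53,226.13,135.88
5,1.21,3.60,0.23,0.55,441.30,128.81
6,1.34,3.86,0.93,0.72,213.06,132.03
7,0.50,4.18,0.28,0.97,430.77,155.68
8,1.12,2.35,0.96,0.20,425.26,129.13
9,0.14,3.25,0.25,0.29,629.30,151.00
10,0.79,3.17,1.18,0.83,188.30,140.20
Mean,0.88,3.37,0.66,0.58,467.67,139.29
SD,0.40,0.60,0.49,0.31,394.86,9.17
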