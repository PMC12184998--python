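# element: B  Z=5  A=10.811
# photon interaction data: mass attenuation coefficients, coherent scattering omitted
# incoherent: free-electron Klein-Nishina x N_A Z/A
# photoelectric: Z^4.44 E^-3 hydrogenic parameterisation with relativistic softening,
#   calibrated to published O/Ca/I values at 100 keV
# columns: energy_keV  photoelectric_cm2g  incoherent_cm2g
10.000000	4.85391822e-01	1.78383254e-01
10.923215	3.73086768e-01	1.77779783e-01
11.931664	2.86811573e-01	1.77126718e-01
13.033213	2.20525617e-01	1.76420560e-01
14.236460	1.69591311e-01	1.75657661e-01
15.550792	1.30448023e-01	1.74834246e-01
16.986465	1.00361819e-01	1.73946426e-01
18.554681	7.72333806e-02	1.72990220e-01
20.267678	5.94505844e-02	1.71961586e-01
22.138822	4.57753361e-02	1.70856455e-01
24.182712	3.52567121e-02	1.69670770e-01
26.415297	2.71642837e-02	1.68400536e-01
28.853998	2.09369327e-02	1.67041870e-01
31.517844	1.61435581e-02	1.65591070e-01
34.427620	1.24529103e-02	1.64044677e-01
37.606031	9.61042984e-03	1.62399551e-01
41.077878	7.42046430e-03	1.60652953e-01
44.870251	5.73261357e-03	1.58802623e-01
49.012742	4.43124379e-03	1.56846873e-01
53.537674	3.42743451e-03	1.54784663e-01
58.480355	2.65279373e-03	1.52615690e-01
63.879351	2.05470722e-03	1.50340458e-01
69.776792	1.59268903e-03	1.47960347e-01
76.218693	1.23557783e-03	1.45477664e-01
83.255321	9.59382552e-04	1.42895675e-01
90.941581	7.45626924e-04	1.40218622e-01
99.337448	5.80077145e-04	1.37451711e-01
108.508435	4.51763835e-04	1.34601076e-01
118.526101	3.52230110e-04	1.31673714e-01
129.468614	2.74953397e-04	1.28677398e-01
141.421356	2.14900738e-04	1.25620554e-01
154.477594	1.68186710e-04	1.22512131e-01
168.739205	1.31810212e-04	1.19361433e-01
184.317469	1.03451878e-04	1.16177958e-01
201.333942	8.13181290e-05	1.12971221e-01
219.921403	6.40210685e-05	1.09750580e-01
240.224887	5.04859702e-05	1.06525077e-01
262.402820	3.98799854e-05	1.03303291e-01
286.628253	3.15571860e-05	1.00093219e-01
313.090217	2.50161803e-05	9.69021830e-02
341.995189	1.98674131e-05	9.37367654e-02
373.568714	1.58079231e-05	9.06027824e-02
408.057155	1.26018487e-05	8.75052835e-02
445.729622	1.00653635e-05	8.44485810e-02
486.880069	8.05502866e-06	8.14363023e-02
531.829590	6.45878142e-06	7.84714610e-02
580.928919	5.18895746e-06	7.55565390e-02
634.561175	4.17688509e-06	7.26935756e-02
693.144843	3.36869330e-06	6.98842561e-02
757.137046	2.72205836e-06	6.71299955e-02
827.037108	2.20367681e-06	6.44320139e-02
903.390452	1.78730043e-06	6.17913996e-02
986.792855	1.45220691e-06	5.92091592e-02
1077.895096	1.18200814e-06	5.66862542e-02
1177.408037	9.63720626e-07	5.42236227e-02
1286.108167	7.87039377e-07	5.18221905e-02
1404.843660	6.43770112e-07	4.94828701e-02
1534.540998	5.27384586e-07	4.72065519e-02
1676.212194	4.32671872e-07	4.49940885e-02
1830.962695	3.55464486e-07	4.28462756e-02
2000.000000	2.92422952e-07	4.07638293e-02
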