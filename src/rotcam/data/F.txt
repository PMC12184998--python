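# element: F  Z=9  A=18.998
# photon interaction data: mass attenuation coefficients, coherent scattering omitted
# incoherent: free-electron Klein-Nishina x N_A Z/A
# photoelectric: Z^4.44 E^-3 hydrogenic parameterisation with relativistic softening,
#   calibrated to published O/Ca/I values at 100 keV
# columns: energy_keV  photoelectric_cm2g  incoherent_cm2g
10.000000	3.75543597e+00	1.82719363e-01
10.923215	2.88654115e+00	1.82101222e-01
11.931664	2.21903718e+00	1.81432283e-01
13.033213	1.70618827e+00	1.80708959e-01
14.236460	1.31211380e+00	1.79927516e-01
15.550792	1.00926546e+00	1.79084086e-01
16.986465	7.76491004e-01	1.78174685e-01
18.554681	5.97548212e-01	1.77195236e-01
20.267678	4.59964204e-01	1.76141598e-01
22.138822	3.54159950e-01	1.75009604e-01
24.182712	2.72778236e-01	1.73795097e-01
26.415297	2.10167794e-01	1.72493986e-01
28.853998	1.61987299e-01	1.71102294e-01
31.517844	1.24901360e-01	1.69616228e-01
34.427620	9.63471268e-02	1.68032246e-01
37.606031	7.43550927e-02	1.66347131e-01
41.077878	5.74115123e-02	1.64558076e-01
44.870251	4.43527522e-02	1.62662769e-01
49.012742	3.42841630e-02	1.60659479e-01
53.537674	2.65177744e-02	1.58547141e-01
58.480355	2.05244435e-02	1.56325445e-01
63.879351	1.58970980e-02	1.53994907e-01
69.776792	1.23225020e-02	1.51556941e-01
76.218693	9.55956247e-03	1.49013909e-01
83.255321	7.42266264e-03	1.46369158e-01
90.941581	5.76885321e-03	1.43627032e-01
99.337448	4.48800840e-03	1.40792863e-01
108.508435	3.49525904e-03	1.37872935e-01
118.526101	2.72517493e-03	1.34874415e-01
129.468614	2.12729146e-03	1.31805265e-01
141.421356	1.66266905e-03	1.28674117e-01
154.477594	1.30124653e-03	1.25490134e-01
168.739205	1.01980459e-03	1.22262849e-01
184.317469	8.00398537e-04	1.19001991e-01
201.333942	6.29151570e-04	1.15717305e-01
219.921403	4.95325658e-04	1.12418378e-01
240.224887	3.90605733e-04	1.09114469e-01
262.402820	3.08548115e-04	1.05814369e-01
286.628253	2.44155311e-04	1.02526267e-01
313.090217	1.93548097e-04	9.92576640e-02
341.995189	1.53712515e-04	9.60153020e-02
373.568714	1.22304580e-04	9.28051387e-02
408.057155	9.74994504e-05	8.96323463e-02
445.729622	7.78748760e-05	8.65013420e-02
486.880069	6.23210837e-05	8.34158414e-02
531.829590	4.99710521e-05	8.03789313e-02
580.928919	4.01465303e-05	7.73931539e-02
634.561175	3.23162110e-05	7.44605981e-02
693.144843	2.60632986e-05	7.15829901e-02
757.137046	2.10603381e-05	6.87617795e-02
827.037108	1.70496633e-05	6.59982158e-02
903.390452	1.38281941e-05	6.32934139e-02
986.792855	1.12356035e-05	6.06484049e-02
1077.895096	9.14509823e-06	5.80641736e-02
1177.408037	7.45622596e-06	5.55416809e-02
1286.108167	6.08925790e-06	5.30818751e-02
1404.843660	4.98079557e-06	5.06856909e-02
1534.540998	4.08033048e-06	4.83540403e-02
1676.212194	3.34754612e-06	4.60877968e-02
1830.962695	2.75019903e-06	4.38877752e-02
2000.000000	2.26245195e-06	4.17547092e-02
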