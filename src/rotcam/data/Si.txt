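# element: Si  Z=14  A=28.086
# photon interaction data: mass attenuation coefficients, coherent scattering omitted
# incoherent: free-electron Klein-Nishina x N_A Z/A
# photoelectric: Z^4.44 E^-3 hydrogenic parameterisation with relativistic softening,
#   calibrated to published O/Ca/I values at 100 keV
# columns: energy_keV  photoelectric_cm2g  incoherent_cm2g
10.000000	1.80655043e+01	1.92259625e-01
10.923215	1.38856905e+01	1.91609209e-01
11.931664	1.06746663e+01	1.90905343e-01
13.033213	8.20760941e+00	1.90144252e-01
14.236460	6.31191632e+00	1.89322008e-01
15.550792	4.85506600e+00	1.88434541e-01
16.986465	3.73530576e+00	1.87477657e-01
18.554681	2.87450243e+00	1.86447068e-01
20.267678	2.21265530e+00	1.85338417e-01
22.138822	1.70368452e+00	1.84147319e-01
24.182712	1.31219822e+00	1.82869400e-01
26.415297	1.01101103e+00	1.81500354e-01
28.853998	7.79239020e-01	1.80035998e-01
31.517844	6.00837315e-01	1.78472341e-01
34.427620	4.63477330e-01	1.76805654e-01
37.606031	3.57684769e-01	1.75032555e-01
41.077878	2.76177768e-01	1.73150089e-01
44.870251	2.13358673e-01	1.71155823e-01
49.012742	1.64923780e-01	1.69047936e-01
53.537674	1.27563610e-01	1.66825307e-01
58.480355	9.87327237e-02	1.64487610e-01
63.879351	7.64729038e-02	1.62035389e-01
69.776792	5.92773288e-02	1.59470130e-01
76.218693	4.59862233e-02	1.56794320e-01
83.255321	3.57066783e-02	1.54011479e-01
90.941581	2.77510370e-02	1.51126179e-01
99.337448	2.15895400e-02	1.48144031e-01
108.508435	1.68139246e-02	1.45071646e-01
118.526101	1.31094392e-02	1.41916566e-01
129.468614	1.02333240e-02	1.38687167e-01
141.421356	7.99826045e-03	1.35392533e-01
154.477594	6.25963934e-03	1.32042306e-01
168.739205	4.90576446e-03	1.28646517e-01
184.317469	3.85031281e-03	1.25215401e-01
201.333942	3.02653021e-03	1.21759212e-01
219.921403	2.38276139e-03	1.18288039e-01
240.224887	1.87900676e-03	1.14811625e-01
262.402820	1.48426903e-03	1.11339217e-01
286.628253	1.17450780e-03	1.07879435e-01
313.090217	9.31062068e-04	1.04440169e-01
341.995189	7.39433219e-04	1.01028515e-01
373.568714	5.88345519e-04	9.76507407e-02
408.057155	4.69020576e-04	9.43122885e-02
445.729622	3.74616668e-04	9.10178062e-02
486.880069	2.99795234e-04	8.77712035e-02
531.829590	2.40385475e-04	8.45757281e-02
580.928919	1.93124666e-04	8.14340554e-02
634.561175	1.55456957e-04	7.83483831e-02
693.144843	1.25377356e-04	7.53205276e-02
757.137046	1.01310642e-04	7.23520141e-02
827.037108	8.20173127e-05	6.94441574e-02
903.390452	6.65204523e-05	6.65981307e-02
986.792855	5.40488095e-05	6.38150188e-02
1077.895096	4.39924453e-05	6.10958578e-02
1177.408037	3.58681345e-05	5.84416591e-02
1286.108167	2.92923420e-05	5.58534204e-02
1404.843660	2.39600900e-05	5.33321251e-02
1534.540998	1.96284076e-05	5.08787328e-02
1676.212194	1.61033524e-05	4.84941628e-02
1830.962695	1.32298175e-05	4.61792722e-02
2000.000000	1.08835128e-05	4.39348332e-02
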