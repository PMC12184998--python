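# element: O  Z=8  A=15.999
# photon interaction data: mass attenuation coefficients, coherent scattering omitted
# incoherent: free-electron Klein-Nishina x N_A Z/A
# photoelectric: Z^4.44 E^-3 hydrogenic parameterisation with relativistic softening,
#   calibrated to published O/Ca/I values at 100 keV
# columns: energy_keV  photoelectric_cm2g  incoherent_cm2g
10.000000	2.64337152e+00	1.92862190e-01
10.923215	2.03177494e+00	1.92209736e-01
11.931664	1.56193308e+00	1.91503664e-01
13.033213	1.20094964e+00	1.90740188e-01
14.236460	9.23569005e-01	1.89915367e-01
15.550792	7.10400494e-01	1.89025118e-01
16.986465	5.46555506e-01	1.88065235e-01
18.554681	4.20601480e-01	1.87031416e-01
20.267678	3.23759022e-01	1.85919291e-01
22.138822	2.49285658e-01	1.84724459e-01
24.182712	1.92002800e-01	1.83442535e-01
26.415297	1.47932641e-01	1.82069198e-01
28.853998	1.14019415e-01	1.80600253e-01
31.517844	8.79154115e-02	1.79031695e-01
34.427620	6.78166938e-02	1.77359785e-01
37.606031	5.23369686e-02	1.75581129e-01
41.077878	4.04107427e-02	1.73692763e-01
44.870251	3.12189591e-02	1.71692247e-01
49.012742	2.41318933e-02	1.69577753e-01
53.537674	1.86652975e-02	1.67348158e-01
58.480355	1.44467193e-02	1.65003135e-01
63.879351	1.11896293e-02	1.62543228e-01
69.776792	8.67354711e-03	1.59969929e-01
76.218693	6.72877274e-03	1.57285733e-01
83.255321	5.22465440e-03	1.54494170e-01
90.941581	4.06057310e-03	1.51599828e-01
99.337448	3.15901368e-03	1.48608333e-01
108.508435	2.46023852e-03	1.45526319e-01
118.526101	1.91819269e-03	1.42361350e-01
129.468614	1.49735522e-03	1.39121830e-01
141.421356	1.17031739e-03	1.35816870e-01
154.477594	9.15919760e-04	1.32456143e-01
168.739205	7.17818769e-04	1.29049711e-01
184.317469	5.63383510e-04	1.25607841e-01
201.333942	4.42846411e-04	1.22140821e-01
219.921403	3.48649198e-04	1.18658768e-01
240.224887	2.74939069e-04	1.15171459e-01
262.402820	2.17180457e-04	1.11688168e-01
286.628253	1.71855732e-04	1.08217543e-01
313.090217	1.36234390e-04	1.04767498e-01
341.995189	1.08194971e-04	1.01345151e-01
373.568714	8.60875934e-05	9.79567903e-02
408.057155	6.86277899e-05	9.46078750e-02
445.729622	5.48144693e-05	9.13030673e-02
486.880069	4.38664856e-05	8.80462893e-02
531.829590	3.51735610e-05	8.48407990e-02
580.928919	2.82582890e-05	8.16892799e-02
634.561175	2.27466937e-05	7.85939367e-02
693.144843	1.83454016e-05	7.55565915e-02
757.137046	1.48239241e-05	7.25787743e-02
827.037108	1.20008955e-05	6.96618041e-02
903.390452	9.73337175e-06	6.68068575e-02
986.792855	7.90850237e-06	6.40150230e-02
1077.895096	6.43704018e-06	6.12873399e-02
1177.408037	5.24827890e-06	5.86248226e-02
1286.108167	4.28609915e-06	5.60284719e-02
1404.843660	3.50587609e-06	5.34992746e-02
1534.540998	2.87205786e-06	5.10381931e-02
1676.212194	2.35626653e-06	4.86461495e-02
1830.962695	1.93580661e-06	4.63240038e-02
2000.000000	1.59249182e-06	4.40725304e-02
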