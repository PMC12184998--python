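# element: Al  Z=13  A=26.982
# photon interaction data: mass attenuation coefficients, coherent scattering omitted
# incoherent: free-electron Klein-Nishina x N_A Z/A
# photoelectric: Z^4.44 E^-3 hydrogenic parameterisation with relativistic softening,
#   calibrated to published O/Ca/I values at 100 keV
# columns: energy_keV  photoelectric_cm2g  incoherent_cm2g
10.000000	1.35321203e+01	1.85831426e-01
10.923215	1.04011951e+01	1.85202758e-01
11.931664	7.99594993e+00	1.84522425e-01
13.033213	6.14797992e+00	1.83786782e-01
14.236460	4.72799482e+00	1.82992029e-01
15.550792	3.63672864e+00	1.82134234e-01
16.986465	2.79796267e+00	1.81209344e-01
18.554681	2.15317059e+00	1.80213213e-01
20.267678	1.65740835e+00	1.79141630e-01
22.138822	1.27615943e+00	1.77990355e-01
24.182712	9.82913283e-01	1.76755163e-01
26.415297	7.57306444e-01	1.75431891e-01
28.853998	5.83695642e-01	1.74016497e-01
31.517844	4.50062321e-01	1.72505120e-01
34.427620	3.47171652e-01	1.70894159e-01
37.606031	2.67926831e-01	1.69180343e-01
41.077878	2.06873315e-01	1.67360818e-01
44.870251	1.59818136e-01	1.65433230e-01
49.012742	1.23537565e-01	1.63395820e-01
53.537674	9.55526112e-02	1.61247505e-01
58.480355	7.39565898e-02	1.58987969e-01
63.879351	5.72826816e-02	1.56617737e-01
69.776792	4.44021893e-02	1.54138248e-01
76.218693	3.44463733e-02	1.51551904e-01
83.255321	2.67463923e-02	1.48862107e-01
90.941581	2.07871512e-02	1.46073277e-01
99.337448	1.61718293e-02	1.43190837e-01
108.508435	1.25946138e-02	1.40221177e-01
118.526101	9.81973738e-03	1.37171587e-01
129.468614	7.66535873e-03	1.34050163e-01
141.421356	5.99116529e-03	1.30865685e-01
154.477594	4.68883630e-03	1.27627473e-01
168.739205	3.67470476e-03	1.24345222e-01
184.317469	2.88410969e-03	1.21028825e-01
201.333942	2.26704830e-03	1.17688195e-01
219.921403	1.78482776e-03	1.14333080e-01
240.224887	1.40748606e-03	1.10972899e-01
262.402820	1.11180439e-03	1.07616592e-01
286.628253	8.79775094e-04	1.04272488e-01
313.090217	6.97419993e-04	1.00948214e-01
341.995189	5.53878767e-04	9.76506279e-02
373.568714	4.40705235e-04	9.43857894e-02
408.057155	3.51323868e-04	9.11589582e-02
445.729622	2.80609814e-04	8.79746269e-02
486.880069	2.24564180e-04	8.48365743e-02
531.829590	1.80062793e-04	8.17479396e-02
580.928919	1.44661680e-04	7.87113087e-02
634.561175	1.16446361e-04	7.57288058e-02
693.144843	9.39149792e-05	7.28021867e-02
757.137046	7.58876015e-05	6.99329254e-02
827.037108	6.14357685e-05	6.71222928e-02
903.390452	4.98277129e-05	6.43714229e-02
986.792855	4.04857223e-05	6.16813644e-02
1077.895096	3.29529168e-05	5.90531185e-02
1177.408037	2.68673324e-05	5.64876629e-02
1286.108167	2.19416789e-05	5.39859619e-02
1404.843660	1.79475100e-05	5.15489661e-02
1534.540998	1.47028263e-05	4.91776030e-02
1676.212194	1.20623536e-05	4.68727610e-02
1830.962695	9.90990775e-06	4.46352688e-02
2000.000000	8.15238820e-06	4.24658726e-02
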