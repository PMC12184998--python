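# element: H  Z=1  A=1.008
# photon interaction data: mass attenuation coefficients, coherent scattering omitted
# incoherent: free-electron Klein-Nishina x N_A Z/A
# photoelectric: Z^4.44 E^-3 hydrogenic parameterisation with relativistic softening,
#   calibrated to published O/Ca/I values at 100 keV
# columns: energy_keV  photoelectric_cm2g  incoherent_cm2g
10.000000	4.10271143e-03	3.82639159e-01
10.923215	3.15346752e-03	3.81344689e-01
11.931664	2.42423762e-03	3.79943840e-01
13.033213	1.86396418e-03	3.78429101e-01
14.236460	1.43344856e-03	3.76792654e-01
15.550792	1.10259500e-03	3.75026397e-01
16.986465	8.48295256e-04	3.73121987e-01
18.554681	6.52805133e-04	3.71070887e-01
20.267678	5.02498355e-04	3.68864427e-01
22.138822	3.86910091e-04	3.66493877e-01
24.182712	2.98002787e-04	3.63950536e-01
26.415297	2.29602585e-04	3.61225831e-01
28.853998	1.76966708e-04	3.58311440e-01
31.517844	1.36451331e-04	3.55199417e-01
34.427620	1.05256610e-04	3.51882342e-01
37.606031	8.12309119e-05	3.48353482e-01
41.077878	6.27205122e-05	3.44606959e-01
44.870251	4.84541728e-05	3.40637929e-01
49.012742	3.74545135e-05	3.36442767e-01
53.537674	2.89699457e-05	3.32019244e-01
58.480355	2.24223950e-05	3.27366710e-01
63.879351	1.73671463e-05	3.22486248e-01
69.776792	1.34619975e-05	3.17380816e-01
76.218693	1.04435614e-05	3.12055362e-01
83.255321	8.10905660e-06	3.06516894e-01
90.941581	6.30231487e-06	3.00774509e-01
99.337448	4.90302684e-06	2.94839375e-01
108.508435	3.81847522e-06	2.88724649e-01
118.526101	2.97717933e-06	2.82445342e-01
129.468614	2.32400793e-06	2.76018124e-01
141.421356	1.81642062e-06	2.69461074e-01
154.477594	1.42157636e-06	2.62793382e-01
168.739205	1.11410872e-06	2.56035010e-01
184.317469	8.74413583e-07	2.49206331e-01
201.333942	6.87330940e-07	2.42327752e-01
219.921403	5.41129779e-07	2.35419349e-01
240.224887	4.26726116e-07	2.28500517e-01
262.402820	3.37080405e-07	2.21589658e-01
286.628253	2.66733022e-07	2.14703927e-01
313.090217	2.11446020e-07	2.07859028e-01
341.995189	1.67926733e-07	2.01069081e-01
373.568714	1.33614420e-07	1.94346564e-01
408.057155	1.06515492e-07	1.87702306e-01
445.729622	8.50761792e-08	1.81145557e-01
486.880069	6.80840851e-08	1.74684100e-01
531.829590	5.45920123e-08	1.68324398e-01
580.928919	4.38589899e-08	1.62071774e-01
634.561175	3.53045796e-08	1.55930604e-01
693.144843	2.84734432e-08	1.49904502e-01
757.137046	2.30078453e-08	1.43996504e-01
827.037108	1.86262924e-08	1.38209227e-01
903.390452	1.51069251e-08	1.32545004e-01
986.792855	1.22745905e-08	1.27005996e-01
1077.895096	9.99077052e-09	1.21594265e-01
1177.408037	8.14572361e-09	1.16311822e-01
1286.108167	6.65234826e-09	1.11160655e-01
1404.843660	5.44138338e-09	1.06142720e-01
1534.540998	4.45764982e-09	1.01259927e-01
1676.212194	3.65710289e-09	9.65141054e-02
1830.962695	3.00451747e-09	9.19069614e-02
2000.000000	2.47166708e-09	8.74400315e-02
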