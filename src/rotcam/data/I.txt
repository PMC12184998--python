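# element: I  Z=53  A=126.904
# photon interaction data: mass attenuation coefficients, coherent scattering omitted
# incoherent: free-electron Klein-Nishina x N_A Z/A
# photoelectric: Z^4.44 E^-3 hydrogenic parameterisation with relativistic softening,
#   calibrated to published O/Ca/I values at 100 keV; K-edge at 33.1694 keV, jump ratio 5.4
# columns: energy_keV  photoelectric_cm2g  incoherent_cm2g
10.000000	2.73178989e+02	1.61083295e-01
10.923215	2.09973595e+02	1.60538349e-01
11.931664	1.61417832e+02	1.59948620e-01
13.033213	1.24112031e+02	1.59310946e-01
14.236460	9.54461546e+01	1.58622035e-01
15.550792	7.34162742e+01	1.57878477e-01
16.986465	5.64837289e+01	1.57076759e-01
18.554681	4.34670216e+01	1.56213288e-01
20.267678	3.34588466e+01	1.55284413e-01
22.138822	2.57624036e+01	1.54286460e-01
24.182712	1.98425118e+01	1.53215765e-01
26.415297	1.52880853e+01	1.52068720e-01
28.853998	1.17833260e+01	1.50841820e-01
31.517844	9.08561018e+00	1.49531722e-01
33.169367	7.81865618e+00	1.48734792e-01
33.169433	4.22204952e+01	1.48734760e-01
34.427620	3.78459542e+01	1.48135301e-01
37.606031	2.92072999e+01	1.46649723e-01
41.077878	2.25517204e+01	1.45072513e-01
44.870251	1.74221306e+01	1.43401632e-01
49.012742	1.34671049e+01	1.41635554e-01
53.537674	1.04164027e+01	1.39773341e-01
58.480355	8.06217240e+00	1.37814719e-01
63.879351	6.24451257e+00	1.35760144e-01
69.776792	4.84038145e+00	1.33610861e-01
76.218693	3.75507579e+00	1.31368953e-01
83.255321	2.91568373e+00	1.29037371e-01
90.941581	2.26605361e+00	1.26619944e-01
99.337448	1.76292709e+00	1.24121374e-01
108.508435	1.37296687e+00	1.21547198e-01
118.526101	1.07047142e+00	1.18903738e-01
129.468614	8.35617810e-01	1.16198010e-01
141.421356	6.53110258e-01	1.13437626e-01
154.477594	5.11140477e-01	1.10630663e-01
168.739205	4.00587742e-01	1.07785526e-01
184.317469	3.14403214e-01	1.04910791e-01
201.333942	2.47135979e-01	1.02015049e-01
219.921403	1.94568046e-01	9.91067525e-02
240.224887	1.53433186e-01	9.61940648e-02
262.402820	1.21200270e-01	9.32847341e-02
286.628253	9.59062404e-02	9.03859816e-02
313.090217	7.60273051e-02	8.75044183e-02
341.995189	6.03795567e-02	8.46459891e-02
373.568714	4.80422582e-02	8.18159460e-02
408.057155	3.82985965e-02	7.90188487e-02
445.729622	3.05899002e-02	7.62585912e-02
486.880069	2.44802409e-02	7.35384492e-02
531.829590	1.96290456e-02	7.08611440e-02
580.928919	1.57698916e-02	6.82289169e-02
634.561175	1.26940769e-02	6.56436094e-02
693.144843	1.02378808e-02	6.31067432e-02
757.137046	8.27267628e-03	6.06195963e-02
827.037108	6.69724981e-03	5.81832702e-02
903.390452	5.43182984e-03	5.57987479e-02
986.792855	4.41343866e-03	5.34669383e-02
1077.895096	3.59227078e-03	5.11887095e-02
1177.408037	2.92886768e-03	4.89649089e-02
1286.108167	2.39191124e-03	4.67963724e-02
1404.843660	1.95649800e-03	4.46839239e-02
1534.540998	1.60278781e-03	4.26283674e-02
1676.212194	1.31494401e-03	4.06304732e-02
1830.962695	1.08030109e-03	3.86909593e-02
2000.000000	8.88709976e-04	3.68104728e-02
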