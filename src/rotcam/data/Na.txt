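# element: Na  Z=11  A=22.99
# photon interaction data: mass attenuation coefficients, coherent scattering omitted
# incoherent: free-electron Klein-Nishina x N_A Z/A
# photoelectric: Z^4.44 E^-3 hydrogenic parameterisation with relativistic softening,
#   calibrated to published O/Ca/I values at 100 keV
# columns: energy_keV  photoelectric_cm2g  incoherent_cm2g
10.000000	7.56442731e+00	1.84545585e-01
10.923215	5.81424658e+00	1.83921266e-01
11.931664	4.46971951e+00	1.83245641e-01
13.033213	3.43670809e+00	1.82515088e-01
14.236460	2.64293935e+00	1.81725835e-01
15.550792	2.03292381e+00	1.80873975e-01
16.986465	1.56405536e+00	1.79955484e-01
18.554681	1.20361792e+00	1.78966246e-01
20.267678	9.26487847e-01	1.77902078e-01
22.138822	7.13370490e-01	1.76758769e-01
24.182712	5.49446497e-01	1.75532124e-01
26.415297	4.23332740e-01	1.74218009e-01
28.853998	3.26284659e-01	1.72812407e-01
31.517844	2.51583909e-01	1.71311489e-01
34.427620	1.94068237e-01	1.69711675e-01
37.606031	1.49770545e-01	1.68009718e-01
41.077878	1.15641756e-01	1.66202782e-01
44.870251	8.93380084e-02	1.64288532e-01
49.012742	6.90572441e-02	1.62265219e-01
53.537674	5.34137125e-02	1.60131770e-01
58.480355	4.13415811e-02	1.57887868e-01
63.879351	3.20209008e-02	1.55534037e-01
69.776792	2.48207322e-02	1.53071705e-01
76.218693	1.92554516e-02	1.50503256e-01
83.255321	1.49511781e-02	1.47832071e-01
90.941581	1.16199746e-02	1.45062538e-01
99.337448	9.04001921e-03	1.42200043e-01
108.508435	7.04036313e-03	1.39250931e-01
118.526101	5.48921293e-03	1.36222443e-01
129.468614	4.28491971e-03	1.33122617e-01
141.421356	3.34904903e-03	1.29960174e-01
154.477594	2.62104982e-03	1.26744368e-01
168.739205	2.05415238e-03	1.23484828e-01
184.317469	1.61221136e-03	1.20191379e-01
201.333942	1.26727532e-03	1.16873863e-01
219.921403	9.97715036e-04	1.13541964e-01
240.224887	7.86781800e-04	1.10205034e-01
262.402820	6.21496360e-04	1.06871950e-01
286.628253	4.91792462e-04	1.03550985e-01
313.090217	3.89856337e-04	1.00249713e-01
341.995189	3.09617088e-04	9.69749445e-02
373.568714	2.46353317e-04	9.37326967e-02
408.057155	1.96389317e-04	9.05281933e-02
445.729622	1.56860307e-04	8.73658956e-02
486.880069	1.25530913e-04	8.42495564e-02
531.829590	1.00654729e-04	8.11822932e-02
580.928919	8.08655806e-05	7.81666739e-02
634.561175	6.50932757e-05	7.52048082e-02
693.144843	5.24982795e-05	7.22984395e-02
757.137046	4.24210126e-05	6.94490317e-02
827.037108	3.43424678e-05	6.66578471e-02
903.390452	2.78535887e-05	6.39260115e-02
986.792855	2.26314352e-05	6.12545666e-02
1077.895096	1.84206125e-05	5.86445066e-02
1177.408037	1.50187834e-05	5.60968024e-02
1286.108167	1.22653532e-05	5.36124116e-02
1404.843660	1.00326211e-05	5.11922784e-02
1534.540998	8.21884956e-06	4.88373237e-02
1676.212194	6.74283080e-06	4.65484298e-02
1830.962695	5.53961798e-06	4.43264196e-02
2000.000000	4.55716818e-06	4.21720343e-02
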