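# element: Cs  Z=55  A=132.905
# photon interaction data: mass attenuation coefficients, coherent scattering omitted
# incoherent: free-electron Klein-Nishina x N_A Z/A
# photoelectric: Z^4.44 E^-3 hydrogenic parameterisation with relativistic softening,
#   calibrated to published O/Ca/I values at 100 keV; K-edge at 35.9846 keV, jump ratio 5.4
# columns: energy_keV  photoelectric_cm2g  incoherent_cm2g
10.000000	3.07472844e+02	1.59614123e-01
10.923215	2.36332885e+02	1.59074147e-01
11.931664	1.81681615e+02	1.58489797e-01
13.033213	1.39692586e+02	1.57857939e-01
14.236460	1.07428103e+02	1.57175311e-01
15.550792	8.26326751e+01	1.56438534e-01
16.986465	6.35744823e+01	1.55644129e-01
18.554681	4.89237068e+01	1.54788533e-01
20.267678	3.76591435e+01	1.53868130e-01
22.138822	2.89965181e+01	1.52879279e-01
24.182712	2.23334656e+01	1.51818349e-01
26.415297	1.72072936e+01	1.50681766e-01
28.853998	1.32625601e+01	1.49466057e-01
31.517844	1.02261833e+01	1.48167907e-01
34.427620	7.88833182e+00	1.46784222e-01
35.984564	6.92780056e+00	1.46058108e-01
35.984636	3.74099035e+01	1.46058075e-01
37.606031	3.28738737e+01	1.45312193e-01
41.077878	2.53827779e+01	1.43749368e-01
44.870251	1.96092389e+01	1.42093727e-01
49.012742	1.51577142e+01	1.40343757e-01
53.537674	1.17240385e+01	1.38498528e-01
58.480355	9.07426698e+00	1.36557770e-01
63.879351	7.02842502e+00	1.34521933e-01
69.776792	5.44802460e+00	1.32392253e-01
76.218693	4.22647377e+00	1.30170793e-01
83.255321	3.28170762e+00	1.27860476e-01
90.941581	2.55052539e+00	1.25465098e-01
99.337448	1.98423828e+00	1.22989315e-01
108.508435	1.54532393e+00	1.20438618e-01
118.526101	1.20485435e+00	1.17819268e-01
129.468614	9.40518104e-01	1.15138218e-01
141.421356	7.35099245e-01	1.12403009e-01
154.477594	5.75307116e-01	1.09621648e-01
168.739205	4.50876009e-01	1.06802460e-01
184.317469	3.53872202e-01	1.03953944e-01
201.333942	2.78160493e-01	1.01084614e-01
219.921403	2.18993381e-01	9.82028421e-02
240.224887	1.72694607e-01	9.53167198e-02
262.402820	1.36415293e-01	9.24339238e-02
286.628253	1.07945946e-01	8.95616096e-02
313.090217	8.55714849e-02	8.67063278e-02
341.995189	6.79593775e-02	8.38739692e-02
373.568714	5.40733013e-02	8.10697376e-02
408.057155	4.31064572e-02	7.82981514e-02
445.729622	3.44300403e-02	7.55630691e-02
486.880069	2.75533976e-02	7.28677364e-02
531.829590	2.20932017e-02	7.02148498e-02
580.928919	1.77495840e-02	6.76066301e-02
634.561175	1.42876432e-02	6.50449020e-02
693.144843	1.15231056e-02	6.25311735e-02
757.137046	9.31119671e-03	6.00667108e-02
827.037108	7.53799717e-03	5.76526054e-02
903.390452	6.11372118e-03	5.52898313e-02
986.792855	4.96748503e-03	5.29792892e-02
1077.895096	4.04323084e-03	5.07218392e-02
1177.408037	3.29654663e-03	4.85183209e-02
1286.108167	2.69218271e-03	4.63695626e-02
1404.843660	2.20210934e-03	4.42763808e-02
1534.540998	1.80399572e-03	4.22395723e-02
1676.212194	1.48001710e-03	4.02599000e-02
1830.962695	1.21591800e-03	3.83380756e-02
2000.000000	1.00027526e-03	3.64747402e-02
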