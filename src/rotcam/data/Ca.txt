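# element: Ca  Z=20  A=40.078
# photon interaction data: mass attenuation coefficients, coherent scattering omitted
# incoherent: free-electron Klein-Nishina x N_A Z/A
# photoelectric: Z^4.44 E^-3 hydrogenic parameterisation with relativistic softening,
#   calibrated to published O/Ca/I values at 100 keV
# columns: energy_keV  photoelectric_cm2g  incoherent_cm2g
10.000000	6.16877092e+01	1.92474810e-01
10.923215	4.74150306e+01	1.91823667e-01
11.931664	3.64504471e+01	1.91119013e-01
13.033213	2.80262656e+01	1.90357071e-01
14.236460	2.15531021e+01	1.89533906e-01
15.550792	1.65784411e+01	1.88645445e-01
16.986465	1.27548310e+01	1.87687491e-01
18.554681	9.81547300e+00	1.86655748e-01
20.267678	7.55548445e+00	1.85545857e-01
22.138822	5.81751791e+00	1.84353425e-01
24.182712	4.48072198e+00	1.83074076e-01
26.415297	3.45226755e+00	1.81703497e-01
28.853998	2.66084296e+00	1.80237503e-01
31.517844	2.05166027e+00	1.78672095e-01
34.427620	1.58262145e+00	1.77003543e-01
37.606031	1.22137493e+00	1.75228459e-01
41.077878	9.43055534e-01	1.73343887e-01
44.870251	7.28549149e-01	1.71347389e-01
49.012742	5.63160041e-01	1.69237142e-01
53.537674	4.35587445e-01	1.67012026e-01
58.480355	3.37139525e-01	1.64671712e-01
63.879351	2.61129618e-01	1.62216746e-01
69.776792	2.02412430e-01	1.59648616e-01
76.218693	1.57027710e-01	1.56969811e-01
83.255321	1.21926471e-01	1.54183856e-01
90.941581	9.47605929e-02	1.51295327e-01
99.337448	7.37211231e-02	1.48309841e-01
108.508435	5.74139794e-02	1.45234017e-01
118.526101	4.47643896e-02	1.42075405e-01
129.468614	3.49434095e-02	1.38842392e-01
141.421356	2.73114083e-02	1.35544071e-01
154.477594	2.13745935e-02	1.32190094e-01
168.739205	1.67515595e-02	1.28790504e-01
184.317469	1.31475420e-02	1.25355547e-01
201.333942	1.03345975e-02	1.21895491e-01
219.921403	8.13634033e-03	1.18420432e-01
240.224887	6.41618525e-03	1.14940127e-01
262.402820	5.06828676e-03	1.11463833e-01
286.628253	4.01055482e-03	1.08000179e-01
313.090217	3.17926835e-03	1.04557064e-01
341.995189	2.52491935e-03	1.01141591e-01
373.568714	2.00900493e-03	9.77600359e-02
408.057155	1.60154981e-03	9.44178472e-02
445.729622	1.27919175e-03	9.11196775e-02
486.880069	1.02370135e-03	8.78694410e-02
531.829590	8.20836717e-04	8.46703892e-02
580.928919	6.59456719e-04	8.15252001e-02
634.561175	5.30833981e-04	7.84360742e-02
693.144843	4.28122113e-04	7.54048298e-02
757.137046	3.45942261e-04	7.24329938e-02
827.037108	2.80061937e-04	6.95218825e-02
903.390452	2.27145296e-04	6.66726704e-02
986.792855	1.84558769e-04	6.38864435e-02
1077.895096	1.50219619e-04	6.11642391e-02
1177.408037	1.22477790e-04	5.85070697e-02
1286.108167	1.00023639e-04	5.59159341e-02
1404.843660	8.18157655e-05	5.33918168e-02
1534.540998	6.70245058e-05	5.09356787e-02
1676.212194	5.49876109e-05	4.85484397e-02
1830.962695	4.51754415e-05	4.62309582e-02
2000.000000	3.71635887e-05	4.39840071e-02
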