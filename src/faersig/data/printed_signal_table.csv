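rank,drug,frequency,ror,ror_lo,ror_hi,prr,chi2,ebgm,eb05,ic,ic025,sig_ror,sig_prr,sig_mgps,sig_bcpnn
1,SEVELAMER CARBONATE,2369,115.51,110.14,121.15,83.78,191709.73,82.63,79.4,6.37,4.70,1,1,1,1
2,PATIROMER,2100,24.90,23.81,26.04,23.07,43942.56,22.8,21.96,4.51,2.84,1,1,1,1
3,SOLIFENACIN SUCCINATE,1135,14.76,13.91,15.67,14.12,13787.01,14.03,13.34,3.81,2.14,1,1,1,1
4,ORLISTAT,1918,11.46,10.94,11.99,11.07,17433.80,10.96,10.55,3.45,1.79,1,1,1,1
5,ERENUMAB,2966,9.65,9.30,10.01,9.38,21897.46,9.24,8.96,3.21,1.54,1,1,1,1
6,NIRAPARIB,3651,9.14,8.84,9.45,8.90,25133.71,8.73,8.49,3.13,1.46,1,1,1,1
7,SEMAGLUTIDE,1214,5.81,5.49,6.15,5.72,4707.24,5.68,5.42,2.51,0.84,1,1,1,1
8,NINTEDANIB,1177,4.56,4.31,4.83,4.51,3201.12,4.48,4.27,2.16,0.50,1,1,1,1
9,CABOZANTINIB,1260,4.06,3.84,4.29,4.02,2846.02,4,3.81,2.00,0.33,1,1,1,1
10,LENALIDOMIDE,7730,3.81,3.72,3.90,3.78,15109.69,3.65,3.58,1.87,0.20,1,1,1,1
11,POMALIDOMIDE,1628,3.71,3.53,3.89,3.67,3149.79,3.65,3.5,1.87,0.20,1,1,1,1
12,ENZALUTAMIDE,1368,3.19,3.02,3.36,3.16,2016.09,3.15,3.01,1.65,-0.01,1,1,1,0
13,VARENICLINE,2059,2.85,2.73,2.98,2.84,2427.64,2.81,2.71,1.49,-0.17,1,1,1,0
14,PALBOCICLIB,2127,2.82,2.70,2.95,2.81,2448.58,2.78,2.68,1.48,-0.19,1,1,1,0
15,DULAGLUTIDE,1066,2.36,2.22,2.50,2.34,819.90,2.34,2.22,1.22,-0.44,1,1,1,0
16,TERIPARATIDE,2300,2.00,1.92,2.09,1.99,1130.24,1.98,1.91,0.99,-0.68,1,0,0,0
17,DALFAMPRIDINE,1099,1.93,1.82,2.05,1.92,484.70,1.92,1.82,0.94,-0.73,1,0,0,0
18,CAPECITABINE,963,1.90,1.78,2.03,1.90,406.31,1.89,1.79,0.92,-0.75,1,0,0,0
19,CLOZAPINE,1227,1.71,1.61,1.81,1.70,354.65,1.70,1.62,0.76,-0.90,1,0,0,0
20,VEDOLIZUMAB,922,1.66,1.56,1.78,1.66,241.48,1.66,1.57,0.73,-0.94,1,0,0,0
21,EXENATIDE,1294,1.57,1.49,1.66,1.57,264.54,1.56,1.49,0.64,-1.02,1,0,0,0
22,DIMETHYL FUMARATE,1517,1.54,1.46,1.62,1.54,281.35,1.53,1.47,0.61,-1.05,1,0,0,0
23,BEVACIZUMAB,904,1.51,1.41,1.61,1.50,152.30,1.50,1.42,0.59,-1.08,1,0,0,0
24,DULOXETINE HYDROCHLORIDE,963,1.28,1.20,1.36,1.27,56.59,1.27,1.21,0.35,-1.32,1,0,0,0
25,ALENDRONATE SODIUM,1135,1.23,1.16,1.31,1.23,49.71,1.23,1.17,0.30,-1.37,1,0,0,0
26,OXYCODONE,1537,1.07,1.02,1.13,1.07,7.06,1.07,1.03,0.10,-1.57,1,0,0,0
27,PREGABALIN,1054,0.87,0.82,0.92,0.87,20.58,0.87,0.83,-0.20,-1.87,0,0,0,0
28,ADALIMUMAB,3720,0.62,0.60,0.64,0.63,821.40,0.63,0.62,-0.66,-2.33,0,0,0,0
29,INFLIXIMAB,905,0.52,0.48,0.55,0.52,407.56,0.52,0.49,-0.94,-2.61,0,0,0,0
30,ETANERCEPT,1007,0.22,0.21,0.23,0.22,2755.52,0.23,0.21,-2.15,-3.81,0,0,0,0
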