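species_code,binomial,n,IL_mean,IL_sd,CLI_mean,CLI_sd,L2M_mean,L2M_sd,VR_mean,VR_sd,F2AV_mean,F2AV_sd,CHI_mean,CHI_sd,L1U_mean,L1U_sd
AC204,Acarus chaetoxysilos,20,185.87,10.93,80.25,5.02,20.61,1.52,0.463,0.051,507.15,85.08,37.5,2.37,9.51,1.03
A17,Acarus farris,20,200.05,20.21,82.22,3.36,22.68,1.61,0.4,0.042,465.01,94.0,38.95,3.94,9.07,1.12
A4,Acarus gracilis,20,192.04,16.49,94.88,13.16,24.29,1.69,0.476,0.065,800.6,207.22,46.8,5.06,11.52,1.44
A1,Acarus immobilis,20,225.81,17.24,89.05,3.53,23.52,1.54,0.444,0.06,621.88,135.49,42.67,3.29,10.39,1.23
A10b,Acarus siro ['H'],20,221.44,13.56,108.33,2.82,30.34,2.01,0.476,0.053,1167.48,194.78,58.48,3.32,14.4,1.34
A15,Acarus siro [SW sp.],20,203.2,13.57,101.07,4.97,27.68,2.28,0.456,0.032,828.98,135.99,49.0,3.82,12.62,1.38
AL2,Aleuroglyphus ovatus,20,211.17,10.46,116.94,5.84,34.0,1.98,0.538,0.048,1839.18,327.53,71.03,5.74,18.24,1.51
C3,Sancassania berlesei,20,260.65,25.89,110.01,7.62,27.32,2.38,0.429,0.048,959.95,167.19,54.03,4.13,11.68,1.31
C10,Cosmoglyphus oudemansi,20,219.75,21.98,92.9,4.7,24.45,1.01,0.426,0.061,700.86,171.41,46.66,4.04,10.38,1.32
C5,Cosmoglyphus hughesae,20,205.87,15.44,93.14,5.37,24.6,2.36,0.427,0.047,735.12,140.19,48.26,4.2,10.45,1.16
KL,Kuzinia laevis,20,331.13,62.25,146.53,7.0,46.13,3.0,0.465,0.036,2544.79,484.11,90.9,7.66,21.45,2.18
L1,Lardoglyphus konoi,20,204.83,31.44,88.62,6.18,19.68,2.45,0.523,0.089,775.59,153.56,43.69,3.23,10.11,0.9
L3,Lardoglyphus zacheri,20,239.59,16.39,98.2,5.12,23.49,1.84,0.476,0.078,763.77,213.33,44.34,3.66,11.12,1.61
LA1,Neosuidasia sp.,20,214.34,24.1,140.36,8.46,37.38,3.0,0.61,0.079,2615.28,695.19,76.67,8.63,22.73,2.68
T34,Madaglyphus legendrei,20,182.49,10.25,85.44,3.65,20.99,1.43,0.475,0.047,674.33,118.13,43.29,3.2,9.96,1.17
R2,Rhizoglyphus echinopus,20,287.59,30.97,119.82,4.88,31.82,2.4,0.448,0.052,1273.05,233.6,61.96,4.25,14.26,1.8
R1,Rhizoglyphus echinopus,20,304.24,17.56,123.29,5.86,33.84,2.12,0.461,0.041,1457.52,235.49,66.15,4.5,15.62,1.75
S5,Suidasia pontifica,20,208.38,25.59,81.55,2.76,20.46,1.84,0.534,0.061,822.56,157.1,46.35,2.67,10.85,0.96
TH4,Thyreophagus sp.,20,356.2,18.91,104.65,4.29,27.45,1.84,0.525,0.059,1300.03,224.42,58.99,4.36,14.33,1.0
TH3,Thyreophagus entomophagus,20,234.65,14.58,94.01,4.1,24.5,1.71,0.509,0.064,1056.24,232.25,54.07,4.32,12.41,1.38
T66,Tyroborus lini,20,231.93,17.37,118.98,4.43,33.2,1.9,0.539,0.04,1797.54,352.1,69.17,6.56,17.9,1.75
T62,Tyrolichus casei,20,260.31,14.7,118.75,5.18,31.88,1.76,0.461,0.042,1130.65,144.81,56.7,2.7,14.66,1.25
T89,Tyrophagus brevicrinatus,20,270.09,14.6,94.01,4.24,25.31,1.73,0.442,0.042,886.84,186.19,53.04,4.47,11.19,1.32
T40,Tyrophagus longior,20,232.52,12.68,100.73,4.51,25.93,1.78,0.449,0.043,950.3,129.78,53.86,2.93,11.61,1.0
T6,Tyrophagus nieswanderi,20,211.78,18.14,95.84,3.71,23.97,1.04,0.473,0.054,803.17,155.17,47.0,3.58,11.31,1.16
T17,Tyrophagus palmarum ['A'],20,216.86,27.4,92.41,3.74,22.16,1.16,0.416,0.054,610.45,146.94,42.78,4.32,9.23,1.3
T32,Tyrophagus palmarum ['B'],20,203.79,12.6,94.29,2.64,23.56,1.3,0.46,0.058,761.44,182.31,46.34,3.77,10.81,1.3
T7,Tyrophagus vanheurni,20,227.36,14.03,100.62,4.43,26.26,1.75,0.431,0.052,727.12,127.71,46.4,2.54,11.32,1.63
T8,Tyrophagus perniciosus ['A'],20,228.9,18.89,106.47,5.26,28.03,1.33,0.426,0.067,785.51,170.74,48.22,3.44,11.94,1.92
T38,Tyrophagus perniciosus ['B'],20,237.55,15.43,115.38,4.87,31.02,2.12,0.487,0.057,1160.39,199.89,56.08,3.34,15.05,1.66
T13,Tyrophagus putrescentiae ['A'],20,188.49,35.24,91.42,3.82,23.8,1.37,0.411,0.06,594.26,123.85,43.16,3.65,9.78,1.57
T9,Tyrophagus putrescentiae ['B'],20,210.92,16.11,91.41,5.6,23.95,1.38,0.473,0.062,696.27,179.11,43.58,3.64,11.33,1.62
T87,Tyrophagus robertsonae,20,172.11,12.31,77.51,5.45,20.08,1.91,0.496,0.052,503.33,58.94,36.21,2.31,9.88,0.55
T44,Tyrophagus similis ['A'],20,211.12,16.16,96.58,5.06,24.88,1.45,0.42,0.04,660.23,89.11,44.92,2.98,10.44,1.02
T21,Tyrophagus similis ['B'],20,219.84,16.11,95.7,3.9,24.81,1.29,0.451,0.04,765.52,125.16,47.33,3.14,11.17,1.01
T11,Tyrophagus savasi,20,194.72,16.04,96.72,5.01,24.24,1.45,0.466,0.04,751.6,121.2,45.4,3.18,11.29,0.99
T90,Tyrophagus tropicus,20,211.8,12.71,86.82,3.78,21.7,1.64,0.509,0.053,755.77,139.38,44.49,4.47,11.01,1.09
Ca4,Carpoglyphus lactis,20,202.63,15.11,81.05,2.71,25.3,1.67,0.355,0.047,302.25,57.23,32.51,2.47,8.94,1.03
CH1,Chortoglyphus arcuatus,20,200.36,7.29,104.55,4.84,32.94,2.97,0.582,0.063,1508.53,214.41,62.25,2.58,19.06,1.63
G3,Glycycometus hughesae,20,171.77,24.43,108.9,4.33,31.82,1.94,0.503,0.062,1452.69,201.87,65.34,2.97,15.96,1.71
G6,Lepidoglyphus destructor,20,225.53,55.54,102.03,3.46,30.1,1.49,0.484,0.064,1522.37,372.91,69.45,7.13,14.52,1.78
G5,Glycyphagus domesticus,20,186.67,35.58,105.44,6.23,28.88,2.31,0.456,0.048,1094.29,213.23,57.86,5.13,13.18,1.7
D4,Dermatophagoides farinae,20,151.58,7.57,87.66,5.92,29.36,3.01,0.514,0.115,1317.21,452.97,64.21,6.2,14.94,2.78
D5,Dermatophagoides microceras,20,119.6,6.67,76.63,2.89,22.99,1.96,0.715,0.118,923.62,205.77,43.11,3.11,16.27,1.81
D3,Dermatophagoides pteronyssinus,20,123.52,8.52,73.49,4.18,22.59,3.2,0.568,0.114,852.17,270.3,47.72,3.69,12.61,1.59
CV1(66),Winterschmidtiidae sp.,20,177.16,11.57,65.16,3.7,17.14,1.18,0.442,0.052,354.13,56.38,32.73,2.0,7.55,0.88
F1,Forcellinia galleriella,20,193.56,22.07,84.08,2.64,22.18,1.25,0.486,0.052,717.3,97.11,45.12,2.3,10.74,0.89
Typical,Typical,20,216.42,2.995,98.17,0.689,26.45,0.239,0.478,0.009,926.53,33.228,51.59,0.621,12.66,0.238
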