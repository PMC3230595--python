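# Species-level morphometrics for 25 iguanian lizards (right side only).
# One row per species x sex. Lengths in mm; se = standard error of the mean.
# fl = front limb, hl = hind limb, d2/d4 = digits II and IV, svl = snout-vent length.
species,sex,n,svl_mean,svl_se,fl_d2_mean,fl_d2_se,fl_d4_mean,fl_d4_se,hl_d2_mean,hl_d2_se,hl_d4_mean,hl_d4_se
Uracentron_superciliosus,male,9,129.71,4.104,10.19,0.475,15.30,0.456,11.90,0.375,27.96,0.609
Uracentron_superciliosus,female,11,123.40,3.560,10.00,0.517,14.24,0.645,11.90,0.428,27.47,0.711
Eurolophosaurus_divaricatus,male,10,71.55,2.121,5.55,0.104,7.80,0.152,7.55,0.184,14.67,0.272
Eurolophosaurus_divaricatus,female,11,59.40,1.066,4.50,0.088,6.32,0.159,5.98,0.147,12.18,0.238
Plica_umbra,male,9,99.55,9.561,8.20,0.678,12.82,0.900,9.59,0.753,22.88,2.374
Plica_umbra,female,10,76.05,3.654,6.29,0.167,10.54,0.360,7.39,0.368,16.55,0.757
Tropidurus_spinulosus,male,12,95.51,3.823,8.86,0.340,12.42,0.388,10.09,0.368,17.56,0.507
Tropidurus_spinulosus,female,6,86.77,3.012,7.65,0.173,10.57,0.267,8.85,0.265,15.71,0.310
Tropidurus_hygomi,male,9,64.78,0.820,5.35,0.142,8.09,0.125,6.96,0.172,15.70,0.235
Tropidurus_hygomi,female,5,47.34,4.440,4.22,0.392,6.38,0.390,5.49,0.364,11.80,0.615
Tropidurus_itambere,male,10,70.82,1.120,5.60,0.114,7.30,0.197,6.76,0.128,10.50,0.200
Tropidurus_itambere,female,10,60.54,1.499,4.75,0.094,6.46,0.129,5.79,0.075,9.49,0.170
Tropidurus_psammonastes,male,9,88.58,1.906,7.36,0.145,10.00,0.259,9.59,0.187,18.35,0.360
Tropidurus_psammonastes,female,10,62.90,2.999,5.72,0.245,7.98,0.320,7.41,0.311,14.15,0.56
Tropidurus_cocorobensis,male,6,64.09,2.443,5.47,0.144,7.80,0.127,7.21,0.100,13.53,0.368
Tropidurus_cocorobensis,female,11,53.35,2.777,4.43,0.136,6.28,0.302,5.50,0.257,11.03,0.340
Tropidurus_etheridgei,male,10,79.71,2.211,5.71,0.139,8.01,0.246,7.55,0.214,13.08,0.278
Tropidurus_etheridgei,female,10,68.25,0.743,4.52,0.110,6.25,0.208,5.93,0.119,10.66,0.139
Tropidurus_montanus,male,10,82.01,2.652,6.66,0.197,9.26,0.253,7.97,0.242,14.52,0.334
Tropidurus_montanus,female,5,72.54,5.156,5.81,1.130,7.95,1.548,6.80,1.332,11.81,2.477
Tropidurus_insulanus,male,10,90.78,2.195,7.42,0.136,9.98,0.193,8.59,0.298,14.58,0.190
Tropidurus_insulanus,female,10,70.86,1.034,5.88,0.158,8.09,0.197,6.85,0.126,11.62,0.193
Tropidurus_oreadicus,male,10,88.64,1.810,7.58,0.130,9.90,0.223,8.98,0.167,15.62,0.284
Tropidurus_oreadicus,female,10,76.61,1.973,6.62,0.146,8.84,0.119,7.31,0.162,13.12,0.161
Tropidurus_hispidus,male,8,87.04,3.022,7.42,0.181,10.13,0.288,9.37,0.270,15.54,0.363
Tropidurus_hispidus,female,10,78.32,1.741,6.73,0.100,9.33,0.132,7.88,0.256,14.20,0.374
Iguana_iguana,male,10,196.20,27.191,17.12,2.272,23.52,2.673,20.35,2.194,41.47,4.146
Iguana_iguana,female,10,234.33,27.280,20.00,2.160,27.48,2.754,22.40,2.215,48.72,4.989
Sauromalus_obesus,male,3,175.58,14.983,11.40,0.572,15.28,1.280,15.05,0.793,25.08,1.597
Sauromalus_obesus,female,4,159.05,2.651,10.45,0.174,12.79,0.174,11.45,0.463,18.96,0.560
Enyalius_perditus,male,10,71.41,2.679,7.01,0.272,10.36,0.266,7.93,0.322,19.11,0.624
Enyalius_perditus,female,9,68.53,3.337,7.00,0.360,10.63,0.296,7.71,0.431,18.54,0.842
Enyalius_iheringii,male,10,83.39,5.037,7.84,0.421,12.01,0.732,8.25,0.487,21.39,1.185
Enyalius_iheringii,female,10,90.42,4.891,8.97,0.627,13.20,0.935,9.84,0.532,23.12,1.219
Anolis_transversalis,male,4,67.99,5.739,4.76,0.474,6.80,0.706,4.70,0.597,12.06,1.219
Anolis_transversalis,female,9,66.67,4.972,4.73,0.384,6.57,0.518,4.20,0.319,11.32,0.997
Anolis_punctatus,male,10,76.80,1.810,5.27,0.246,7.41,0.223,4.76,0.166,12.73,0.362
Anolis_punctatus,female,10,70.70,1.794,4.93,0.152,7.03,0.222,4.41,0.130,11.98,0.349
Anolis_olssoni,male,10,43.46,0.583,2.60,0.098,4.14,0.096,3.54,0.103,9.01,0.128
Anolis_olssoni,female,10,38.66,0.470,2.12,0.126,3.39,0.05,2.96,0.090,8.22,0.224
Anolis_nitens,male,10,60.81,2.044,5.09,0.250,7.43,0.306,4.60,0.19,12.76,0.486
Anolis_nitens,female,8,58.89,5.079,5.03,0.818,6.81,1.120,5.30,0.907,12.42,2.060
Anolis_ortonii,male,10,51.73,0.626,3.22,0.097,5.23,0.192,3.37,0.122,8.44,0.242
Anolis_ortonii,female,10,46.53,0.651,2.94,0.101,4.63,0.131,3.17,0.120,7.88,0.123
Anolis_fuscoauratus,male,10,55.75,4.693,3.85,0.506,5.92,0.529,4.25,0.503,9.86,1.036
Anolis_fuscoauratus,female,10,48.30,1.910,3.04,0.19,5.06,0.192,3.14,0.217,8.80,0.274
Polychrus_acutirostris,male,10,108.24,2.458,4.95,0.147,7.15,0.213,5.95,0.130,9.39,0.342
Polychrus_acutirostris,female,10,128.10,1.865,5.54,0.090,7.78,0.213,6.47,0.223,9.56,0.205
Polychrus_marmoratus,male,10,107.45,2.941,5.82,0.132,8.70,0.281,7.21,0.237,12.62,0.379
Polychrus_marmoratus,female,10,121.50,4.040,6.16,0.202,9.49,0.150,7.72,0.372,13.96,0.322
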