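H KYTJ820101
D Hydropathy index (Kyte-Doolittle, 1982)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   1.8  -4.5  -3.5  -3.5  2.5  -3.5  -3.5  -0.4  -3.2  4.5
   3.8  -3.9  1.9  2.8  -1.6  -0.8  -0.7  -0.9  -1.3  4.2
//
H FAUJ880103
D Normalized van der Waals volume (Fauchere et al., 1988)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   1  6.13  2.95  2.78  2.43  3.95  3.78  0  4.66  4
   4  4.77  4.43  5.89  2.72  1.6  2.6  8.08  6.47  3
//
H FASG760101
D Molecular weight (Fasman, 1976)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   89.09  174.2  132.12  133.1  121.15  146.15  147.13  75.07  155.16  131.17
   131.17  146.19  149.21  165.19  115.13  105.09  119.12  204.23  181.19  117.15
//
H SYNHYD0001
D Synthetic hydrophobicity scale (S/M/L trisection at 0.5 and 2.5)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   1.2  0  0.25  0.1  2.6  0.3  0.15  1  1.8  3.6
   3.8  0.05  2.9  4.2  1.5  0.6  0.8  4.5  2.2  3.2
//
H SYNCHG0001
D Synthetic net charge at neutral pH
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0  1  0  -1  0  0  -1  0  0.1  0
   0  1  0  0  0  0  0  0  0  0
//
H SYNARO0001
D Synthetic aromaticity indicator
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0  0  0  0  0  0  0  0  0.5  0
   0  0  0  1  0  0  0  1  1  0
//
H SYNPOL0001
D Synthetic polarity indicator
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0  1  1  1  0  1  1  0  1  0
   0  1  0  0  0  1  1  0  1  0
//
H SYNSML0001
D Synthetic residue smallness score
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.9  0.1  0.25  0.3  0.6  0.1  0.1  1  0.1  0.1
   0.1  0.1  0.1  0.1  0.5  0.8  0.55  0.1  0.1  0.3
//
H SYNHEL0001
D Synthetic helix propensity (fixed pseudo-random scale)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   1.534  1.85  1.101  0.621  0.634  0.567  1.356  1.982  0.714  0.892
   1.088  1.304  0.033  0.925  0.507  1.684  1.967  0.032  0.058  1.107
//
H SYNCOI0001
D Synthetic coil propensity (fixed pseudo-random scale)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   1.847  1.084  1.239  1.598  1.504  0.469  1.848  0.849  0.24  1.867
   0.39  0.886  0.616  1.146  0.402  0.548  0.088  0.041  0.869  0.099
//
H SYNBRN0001
D Synthetic branched/beta-aliphatic indicator
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0  0  0  0  0  0  0  0  0  1
   0.8  0  0  0  0  0  0.6  0  0  1
//
H SYNNA00001
D Synthetic incomplete scale with NA values (W, Y missing)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   1  1  1  1  1  1  1  1  1  1
   1  1  1  1  1  1  1  NA  NA  1
//
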