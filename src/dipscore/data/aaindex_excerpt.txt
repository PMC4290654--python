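H SNEP660103
D Principal component III (Sneath, 1966)
R PMID:5968986
A Sneath, P.H.A.
T Relations between chemical structure and biological activity in peptides
J J. Theor. Biol. 12, 157-195 (1966)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   -0.110   0.079  -0.136  -0.285  -0.184  -0.067  -0.246  -0.073   0.320   0.001
   -0.008   0.049  -0.041   0.438  -0.016  -0.153  -0.208   0.493   0.381  -0.155
//
H TAKK010101
D Side-chain contribution to protein stability (kJ/mol) (Takano-Yutani, 2001)
R PMID:11297669
A Takano, K. and Yutani, K.
T A new scale for side-chain contribution to protein stability based on the
  empirical stability analysis of mutant proteins
J Protein Eng. 14, 525-528 (2001)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
      9.8     7.3     3.6     4.9     3.0     2.4     4.4     0.0    11.9    17.2
     17.0    10.5    11.9    23.0    15.0     2.6     6.9    24.2    17.2    15.3
//
H KARP850101
D Flexibility parameter for no rigid neighbors (Karplus-Schulz, 1985)
R
A Karplus, P.A. and Schulz, G.E.
T Prediction of chain flexibility in proteins
J Naturwissenschaften 72, 212-213 (1985)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.041   1.038   1.117   1.033   0.960   1.165   1.094   1.142   0.982   1.002
    0.967   1.093   0.947   0.930   1.055   1.169   1.073   0.925   0.961   0.982
//
H TSTNA00001
D Synthetic scale with a missing value (packaged for parser tests)
R
A none
T none
J none
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
      1.0     2.0     3.0     4.0     5.0     6.0     7.0     8.0     9.0    10.0
     11.0    12.0    13.0    14.0    15.0      NA    17.0    18.0    19.0    20.0
//
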