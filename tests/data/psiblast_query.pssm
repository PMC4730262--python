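
Last position-specific scoring matrix computed, weighted observed percentages rounded down, information per position, and relative weight of gapless real matches to pseudocounts
           A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V   A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V
    1 M   -1 -1 -2 -3 -2  0 -2 -3 -2  1  2 -1  6  0 -3 -2 -1 -2 -1  1    0   0   0   0   0   0   0   0   0   0   0   0 100   0   0   0   0   0   0   0  0.34 0.00
    2 K   -1  4  0 -1 -3  1  1 -2 -1 -3 -3  4 -1 -3 -1  0 -1 -3 -2 -2    0  27   0   0   0   0   0   0   0   0   0  73   0   0   0   0   0   0   0   0  0.51 0.00
    3 T    0 -1  0 -1 -1 -1 -1 -1 -2 -1 -2 -1 -1 -2 -1  2  4 -3 -2  0    0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  26  74   0   0   0  0.41 0.00
    4 A    4 -2 -2 -2  0 -1 -1  0 -2 -1 -2 -1 -1 -2 -1  1  0 -3 -2  0  100   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.40 0.00
    5 Y   -2 -2 -2 -3 -3 -2 -2 -3  2 -1 -1 -2 -1  3 -3 -2 -2  2  7 -1    0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0 100   0  0.85 0.00
    6 I   -1 -3 -3 -3 -1 -3 -3 -4 -3  4  1 -3  1  0 -3 -2 -1 -3 -1  3    0   0   0   0   0   0   0   0   0  76   0   0   0   0   0   0   0   0   0  24  0.36 0.00
    7 A    4 -2 -2 -2  0 -1 -1  0 -2 -1 -2 -1 -1 -2 -1  1  0 -3 -2  0  100   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.40 0.00
    8 K   -1  2  0 -1 -3  1  1 -2 -1 -3 -3  5 -1 -3 -1  0 -1 -3 -2 -2    0   0   0   0   0   0   0   0   0   0   0 100   0   0   0   0   0   0   0   0  0.51 0.00
    9 Q   -1  1  0  0 -3  6  2 -2  0 -3 -2  1  0 -3 -1  0 -1 -2 -2 -2    0   0   0   0   0 100   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.65 0.00
   10 R   -2  6  0 -2 -4  1  0 -2  0 -3 -2  2 -1 -3 -2 -1 -1 -3 -2 -3    0 100   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.74 0.00
   11 Q   -1  1  0  0 -3  6  2 -2  0 -3 -2  1  0 -3 -1  0 -1 -2 -2 -2    0   0   0   0   0 100   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.65 0.00
   12 I   -1 -3 -4 -3 -1 -3 -3 -4 -3  4  3 -3  1  0 -3 -3 -1 -2 -1  2    0   0   0   0   0   0   0   0   0  73  27   0   0   0   0   0   0   0   0   0  0.36 0.00
   13 S    1 -1  1  0 -1  0  0  0 -1 -3 -3  0 -2 -3 -1  4  1 -3 -2 -2    0   0   0   0   0   0   0   0   0   0   0   0   0   0   0 100   0   0   0   0  0.45 0.00
   14 F   -2 -3 -3 -4 -3 -3 -3 -3 -1  0  0 -3  0  6 -4 -3 -2  1  3 -1    0   0   0   0   0   0   0   0   0   0   0   0   0 100   0   0   0   0   0   0  0.73 0.00
   15 V    0 -3 -3 -3 -1 -2 -3 -3 -3  3  1 -2  1 -1 -3 -2  0 -3 -1  4    0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0 100  0.34 0.00
   16 K   -1  2  0 -1 -3  1  1 -2 -1 -3 -3  5 -1 -3 -1  0 -1 -3 -2 -2    0   0   0   0   0   0   0   0   0   0   0 100   0   0   0   0   0   0   0   0  0.51 0.00
   17 S    1 -1  3  0 -1  0  0  0  0 -3 -3  0 -2 -3 -1  4  1 -3 -2 -2    0   0  26   0   0   0   0   0   0   0   0   0   0   0   0  74   0   0   0   0  0.41 0.00
   18 H   -2  0  1 -1 -3  0  0 -2  8 -3 -3 -1 -2 -1 -2 -1 -2 -3  2 -3    0   0   0   0   0   0   0   0 100   0   0   0   0   0   0   0   0   0   0   0  0.85 0.00
   19 F   -2 -3 -3 -4 -3 -3 -3 -3 -1  0  0 -3  0  6 -4 -3 -2  1  3 -1    0   0   0   0   0   0   0   0   0   0   0   0   0 100   0   0   0   0   0   0  0.73 0.00
   20 S    2 -1  0 -1 -1  0  0  0 -1 -2 -2  0 -1 -2 -1  4  1 -3 -2 -1   27   0   0   0   0   0   0   0   0   0   0   0   0   0   0  73   0   0   0   0  0.38 0.00
   21 R   -2  6  0 -2 -4  1  0 -2  0 -3 -2  2 -1 -3 -2 -1 -1 -3 -2 -3    0 100   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.74 0.00
   22 Q   -1  1  0  0 -3  6  2 -2  0 -3 -2  1  0 -3 -1  0 -1 -2 -2 -2    0   0   0   0   0 100   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.65 0.00

                      K         Lambda
Standard Ungapped    0.1265     0.3278
Standard Gapped      0.0410     0.2670
PSI Ungapped         0.1265     0.3278
PSI Gapped           0.0410     0.2670
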