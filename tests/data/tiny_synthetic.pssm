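
Last position-specific scoring matrix computed, weighted observed percentages rounded down, information per position, and relative weight of gapless real matches to pseudocounts
           A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V   A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V
    1 M    -9   5  10   3   6   5  -1   8  -9   4  -9  -6   1  -1   5   6   0   7  -1  -8    0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.00 0.00
    2 K     0   8  -6  -7  -3   1   9   3  -2   7  -1   1  -1   6  -9  -9   8  -5   3   7    0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.00 0.00
    3 L    -7   0  -6   4   5  -1  -3  10  -1   8   6   4   5  -9  -3 -10   1   5   4  -7    0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.00 0.00

                      K         Lambda
Standard Ungapped    0.1347     0.3176
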