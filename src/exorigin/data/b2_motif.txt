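MEME version 4

ALPHABET= ACGT

Background letter frequencies
A 0.3100 C 0.1900 G 0.1900 T 0.3100

MOTIF B2
# ANCHOR 5
letter-probability matrix: alength= 4 w= 13 nsites= 100 E= 0
0.920000 0.020000 0.030000 0.030000
0.930000 0.020000 0.020000 0.030000
0.930000 0.020000 0.020000 0.030000
0.500000 0.020000 0.030000 0.450000
0.040000 0.020000 0.020000 0.920000
0.010000 0.010000 0.010000 0.970000
0.050000 0.020000 0.030000 0.900000
0.930000 0.020000 0.020000 0.030000
0.040000 0.030000 0.890000 0.040000
0.920000 0.020000 0.030000 0.030000
0.920000 0.020000 0.030000 0.030000
0.040000 0.030000 0.890000 0.040000
0.450000 0.030000 0.070000 0.450000
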