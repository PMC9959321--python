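MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.250000 C 0.250000 G 0.250000 T 0.250000

MOTIF TOY_GC_BOX
letter-probability matrix: alength= 4 w= 10 nsites= 1000000 E= 0
 0.040000 0.040000 0.880000 0.040000
 0.040000 0.040000 0.880000 0.040000
 0.040000 0.040000 0.880000 0.040000
 0.040000 0.040000 0.880000 0.040000
 0.040000 0.880000 0.040000 0.040000
 0.040000 0.040000 0.880000 0.040000
 0.040000 0.040000 0.880000 0.040000
 0.040000 0.040000 0.880000 0.040000
 0.040000 0.040000 0.880000 0.040000
 0.040000 0.880000 0.040000 0.040000

MOTIF TOY_TATA
letter-probability matrix: alength= 4 w= 11 nsites= 1000000 E= 0
 0.040000 0.880000 0.040000 0.040000
 0.040000 0.040000 0.040000 0.880000
 0.880000 0.040000 0.040000 0.040000
 0.040000 0.040000 0.040000 0.880000
 0.880000 0.040000 0.040000 0.040000
 0.880000 0.040000 0.040000 0.040000
 0.880000 0.040000 0.040000 0.040000
 0.460000 0.040000 0.040000 0.460000
 0.040000 0.040000 0.880000 0.040000
 0.040000 0.040000 0.880000 0.040000
 0.040000 0.880000 0.040000 0.040000

MOTIF TOY_CAAT
letter-probability matrix: alength= 4 w= 12 nsites= 1000000 E= 0
 0.880000 0.040000 0.040000 0.040000
 0.040000 0.040000 0.880000 0.040000
 0.040000 0.880000 0.040000 0.040000
 0.040000 0.880000 0.040000 0.040000
 0.880000 0.040000 0.040000 0.040000
 0.880000 0.040000 0.040000 0.040000
 0.040000 0.040000 0.040000 0.880000
 0.040000 0.880000 0.040000 0.040000
 0.880000 0.040000 0.040000 0.040000
 0.040000 0.040000 0.880000 0.040000
 0.880000 0.040000 0.040000 0.040000
 0.040000 0.040000 0.880000 0.040000

MOTIF TOY_EBOX
letter-probability matrix: alength= 4 w= 12 nsites= 1000000 E= 0
 0.460000 0.040000 0.460000 0.040000
 0.880000 0.040000 0.040000 0.040000
 0.040000 0.880000 0.040000 0.040000
 0.040000 0.880000 0.040000 0.040000
 0.880000 0.040000 0.040000 0.040000
 0.040000 0.880000 0.040000 0.040000
 0.040000 0.040000 0.880000 0.040000
 0.040000 0.040000 0.040000 0.880000
 0.040000 0.040000 0.880000 0.040000
 0.040000 0.040000 0.880000 0.040000
 0.040000 0.040000 0.040000 0.880000
 0.040000 0.880000 0.040000 0.040000

MOTIF TOY_GATA_PAIR
letter-probability matrix: alength= 4 w= 13 nsites= 1000000 E= 0
 0.880000 0.040000 0.040000 0.040000
 0.040000 0.040000 0.880000 0.040000
 0.880000 0.040000 0.040000 0.040000
 0.040000 0.040000 0.040000 0.880000
 0.880000 0.040000 0.040000 0.040000
 0.880000 0.040000 0.040000 0.040000
 0.040000 0.040000 0.880000 0.040000
 0.880000 0.040000 0.040000 0.040000
 0.040000 0.040000 0.880000 0.040000
 0.880000 0.040000 0.040000 0.040000
 0.040000 0.040000 0.040000 0.880000
 0.880000 0.040000 0.040000 0.040000
 0.880000 0.040000 0.040000 0.040000

MOTIF TOY_CRE_LONG
letter-probability matrix: alength= 4 w= 14 nsites= 1000000 E= 0
 0.040000 0.040000 0.040000 0.880000
 0.040000 0.040000 0.040000 0.880000
 0.040000 0.040000 0.880000 0.040000
 0.880000 0.040000 0.040000 0.040000
 0.040000 0.880000 0.040000 0.040000
 0.040000 0.040000 0.880000 0.040000
 0.040000 0.040000 0.040000 0.880000
 0.040000 0.880000 0.040000 0.040000
 0.880000 0.040000 0.040000 0.040000
 0.040000 0.040000 0.040000 0.880000
 0.040000 0.040000 0.880000 0.040000
 0.880000 0.040000 0.040000 0.040000
 0.040000 0.880000 0.040000 0.040000
 0.040000 0.040000 0.880000 0.040000

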