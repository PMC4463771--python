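# Monoisotopic atomic masses (u), CODATA/IUPAC values. version 1
# symbol	mass
C	12.000000
H	1.00782503
N	14.00307401
O	15.99491462
P	30.97376200
e-	0.00054858
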