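gene	bc	cc
INS	0.3211	0.6250
AKT1	0.2435	0.5128
TCF7L2	0.2003	0.5714
KCNJ11	0.1342	0.5000
UBC	0.1097	0.4878
PPARG	0.0952	0.5128
GCGR	0.0780	0.4762
INSR	0.0775	0.5000
IAPP	0.0526	0.4348
SOCS3	0.0518	0.4348
EP300	0.0443	0.4167
PPARA	0.0311	0.4082
WFS1	0.0186	0.4444
APOE	0.0163	0.3846
FOXO1	0.0096	0.3704
STAT3	0.0066	0.3509
PTH	0.0044	0.3509
CTLA4	0.0000	0.3448
MTNR1B	0.0000	0.3922
PRKACA	0.0000	0.3390
SOD3	0.0000	0.3448
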