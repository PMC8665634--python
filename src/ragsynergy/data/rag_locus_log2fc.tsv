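locus	gene	comparison	timepoint	log2FC
Rag1	Glyma.07G064400	Rag1vSusc	6
Rag1	Glyma.07G064400	Rag1/2vSusc	6	1.25139
Rag1	Glyma.07G064400	Rag1/2vRag2	6
Rag1	Glyma.07G064400	Rag1vSusc	12	0.90248
Rag1	Glyma.07G064400	Rag1/2vSusc	12	0.92288
Rag1	Glyma.07G064400	Rag1/2vRag2	12
Rag1	Glyma.07G063700	Rag1vSusc	6	2.48920
Rag1	Glyma.07G063700	Rag1/2vSusc	6	3.22033
Rag1	Glyma.07G063700	Rag1/2vRag2	6	3.37710
Rag1	Glyma.07G063700	Rag1vSusc	12	3.01142
Rag1	Glyma.07G063700	Rag1/2vSusc	12	3.13451
Rag1	Glyma.07G063700	Rag1/2vRag2	12	3.24709
Rag1	Glyma.07G063600	Rag1vSusc	6
Rag1	Glyma.07G063600	Rag1/2vSusc	6	-1.97796
Rag1	Glyma.07G063600	Rag1/2vRag2	6	-1.97610
Rag1	Glyma.07G063600	Rag1vSusc	12	-1.84461
Rag1	Glyma.07G063600	Rag1/2vSusc	12	-1.70881
Rag1	Glyma.07G063600	Rag1/2vRag2	12	-1.85213
Rag1	Glyma.07G063300	Rag1vSusc	6	-0.92302
Rag1	Glyma.07G063300	Rag1/2vSusc	6	-1.40440
Rag1	Glyma.07G063300	Rag1/2vRag2	6	-1.28773
Rag1	Glyma.07G063300	Rag1vSusc	12	-1.29225
Rag1	Glyma.07G063300	Rag1/2vSusc	12	-1.14970
Rag1	Glyma.07G063300	Rag1/2vRag2	12	-1.24997
Rag1	Glyma.07G063100	Rag1vSusc	6
Rag1	Glyma.07G063100	Rag1/2vSusc	6
Rag1	Glyma.07G063100	Rag1/2vRag2	6
Rag1	Glyma.07G063100	Rag1vSusc	12	0.57516
Rag1	Glyma.07G063100	Rag1/2vSusc	12	0.68902
Rag1	Glyma.07G063100	Rag1/2vRag2	12	0.72726
Rag1	Glyma.07G062400	Rag1vSusc	6
Rag1	Glyma.07G062400	Rag1/2vSusc	6
Rag1	Glyma.07G062400	Rag1/2vRag2	6
Rag1	Glyma.07G062400	Rag1vSusc	12
Rag1	Glyma.07G062400	Rag1/2vSusc	12
Rag1	Glyma.07G062400	Rag1/2vRag2	12	-0.62122
Rag2	Glyma.13G190900	Rag2vSusc	6	-1.33233
Rag2	Glyma.13G190900	Rag1/2vSusc	6	-1.35883
Rag2	Glyma.13G190900	Rag1/2vRag1	6	-1.44740
Rag2	Glyma.13G190900	Rag2vSusc	12	-1.70851
Rag2	Glyma.13G190900	Rag1/2vSusc	12	-1.75952
Rag2	Glyma.13G190900	Rag1/2vRag1	12	-1.49086
Rag2	Glyma.13G190800	Rag2vSusc	6	-1.85926
Rag2	Glyma.13G190800	Rag1/2vSusc	6	-1.95789
Rag2	Glyma.13G190800	Rag1/2vRag1	6	-1.81795
Rag2	Glyma.13G190800	Rag2vSusc	12	-1.84813
Rag2	Glyma.13G190800	Rag1/2vSusc	12	-1.62494
Rag2	Glyma.13G190800	Rag1/2vRag1	12	-1.57998
Rag2	Glyma.13G190400	Rag2vSusc	6	-1.70636
Rag2	Glyma.13G190400	Rag1/2vSusc	6	-1.87610
Rag2	Glyma.13G190400	Rag1/2vRag1	6	-1.56779
Rag2	Glyma.13G190400	Rag2vSusc	12	-2.00623
Rag2	Glyma.13G190400	Rag1/2vSusc	12	-1.80790
Rag2	Glyma.13G190400	Rag1/2vRag1	12	-1.67855
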