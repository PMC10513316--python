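Name	Size	Sequence	Section	Role
Primer F1	20	TCCTTTACTTACTACACCTC	selection	opposite_primer
Primer F2	20	&&&&&&&&&&&&&&CACCTCAGATATTTTTCTTC	selection	opposite_primer
Primer F3	21	&&&&&&&&&&&&&&CACCTCAGATATTTTTCTTCA	selection	opposite_primer
Primer F4	18	&&TTTTGGTCTAGCCACAGA	selection	allele_primer
Primer F5	19	&ATTTTGGTCTAGCCACAGA	selection	allele_primer
Primer F6	20	GATTTTGGTCTAGCCACAGA	selection	allele_primer
Primer R1	17	&&ACTCCATCGAGATTTCT	selection	allele_primer
Primer R2	18	&CACTCCATCGAGATTTCT	selection	allele_primer
Primer R3	19	CCACTCCATCGAGATTTCT	selection	allele_primer
Primer R4	19	&TTAATTAATGGAGAAATGG	selection	opposite_primer
Primer R5	20	TTTAATTAATGGAGAAATGG	selection	opposite_primer
Primer R6	20	&&ATTCTTACCATCCACAAAAT	selection	opposite_primer
Primer R7	20	&AATTCTTACCATCCACAAAA	selection	opposite_primer
Primer R8	20	CAATTCTTACCATCCACAAA	selection	opposite_primer
Blocker BR1	21	&TCGAGATTTCACTGTGGCTAG-P	selection	blocker
Blocker BR2	23	ATCGAGATTTCACTGTGGCTAGA-P	selection	blocker
Blocker BR3	24	ATCGAGATTTCACTGTGGCTAGAC-P	selection	blocker
Blocker BF1	21	&&CTAGCCACAGTGAAATCTCGA-P	selection	blocker
Blocker BF2	23	&TCTAGCCACAGTGAAATCTCGAT-P	selection	blocker
Blocker BF3	25	GTCTAGCCACAGTGAAATCTCGATG-P	selection	blocker
Primer_Fw_TA	21	CACCTCAGATATTTTTCTTCA	ta_cloning	opposite_primer
Primer_Rv_TA	20	CAATTCTTACCATCCACAAA	ta_cloning	opposite_primer
BRAF_Fw_BC1	60	P-ATCGCCTACCGTGAC-AAGAAAGTTGTCGGTGTCTTTGTG-CACCTCAGATATTTTTCTTCA	nanopore	barcoded_primer
BRAF_Fw_BC2	60	P-ATCGCCTACCGTGAC-TCGATTCCGTTTGTAGTCGTCTGT-CACCTCAGATATTTTTCTTCA	nanopore	barcoded_primer
BRAF_Fw_BC3	60	P-ATCGCCTACCGTGAC-GAGTCTTGTGTCCCAGTTACCAGG-CACCTCAGATATTTTTCTTCA	nanopore	barcoded_primer
BRAF_Fw_BC4	60	P-ATCGCCTACCGTGAC-TTCGGATTCTATCGTGTTTCCCTA-CACCTCAGATATTTTTCTTCA	nanopore	barcoded_primer
BRAF_Fw_BC5	60	ATCGCCTACCGTGAC-CTTGTCCAGGGTTTGTGTAACCTT-CACCTCAGATATTTTTCTTCA	nanopore	barcoded_primer
BRAF_Fw_BC6	60	ATCGCCTACCGTGAC-TTCTCGCAAAGGCAGAAAGTAGTC-CACCTCAGATATTTTTCTTCA	nanopore	barcoded_primer
BRAF_Rv	20	P-CAATTCTTACCATCCACAAA	nanopore	opposite_primer
Primer_Std_Fw	20	ATTTCAAGCCCCCAAAATCT	standards	opposite_primer
Primer_Std_Rv	20	CTGCAGATCGTACCTGCTGA	standards	opposite_primer
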