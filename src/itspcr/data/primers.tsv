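# Built-in rDNA/ITS primer registry (5'->3' IUPAC sequences).
name	sequence	description
ITS1	TCCGTAGGTGAACCTGCGG	forward, SSU 3' end (White et al. 1990)
ITS1-F	CTTGGTCATTTAGAGGAAGTAA	forward, fungal-specific, SSU 3' end (Gardes & Bruns 1993)
ITS2	GCTGCGTTCTTCATCGATGC	reverse, 5.8S (White et al. 1990)
ITS3	GCATCGATGAAGAACGCAGC	forward, 5.8S (White et al. 1990)
ITS4	TCCTCCGCTTATTGATATGC	reverse, LSU 5' end (White et al. 1990)
ITS4-B	CAGGAGACTTGTACACGGTCCAG	reverse, basidiomycete-specific, LSU (Gardes & Bruns 1993)
ITS5	GGAAGTAAAAGTCGTAACAAGG	forward, SSU 3' end (White et al. 1990)
NS7	GAGGCAATAACAGGTCTGTGATGC	forward, SSU (White et al. 1990)
LR3	CCGTGTTTCAAGACGGG	reverse, LSU (Vilgalys lab)
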