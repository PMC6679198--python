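gene	category	source	interaction_type
TRIB2	KINASE	synthetic-dGene	none
TRIB2	DRUGGABLE GENOME	synthetic-HopkinsGroom	none
TRIM7	DRUGGABLE GENOME	synthetic-HopkinsGroom	none
DUSP4	PHOSPHATASE	synthetic-dGene	none
PKM2	ENZYME	synthetic-dGene	inhibitor
VSIG4	CLINICALLY ACTIONABLE	synthetic-CIViC	none
BMP4	GROWTH FACTOR	synthetic-dGene	none
IL1RN	DRUGGABLE GENOME	synthetic-HopkinsGroom	agonist
EGFR	KINASE	synthetic-dGene	inhibitor
KRAS	ENZYME	synthetic-dGene	none
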