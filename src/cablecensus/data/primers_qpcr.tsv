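name	sequence	orientation	target	reference
Eub338	ACTCCTACGGGAGGCAGCAG	forward	TB	universal bacterial forward
Eub518	ATTACCGCGGCTGCTGG	reverse	TB	universal bacterial reverse
DSBB280F	CGATGGTTAGCGGGTCTG	forward	DSB	Desulfobulbaceae forward
DSBB280wF	CGATGGTTARCGGGTCTG	forward	DSB	Desulfobulbaceae forward, wobble at position 10
SRB385R	CGGCGTCGCTGCGTCAGG	reverse	DSB	sulfate-reducer reverse
ELF645F	CTTGGCTTGAGTATCAGAGG	forward	CB	Ca. Electrothrix forward
ELF645wF	CYTGGCTTGAGTATCAGAGG	forward	CB	Ca. Electrothrix forward, wobble at position 2
CB836R	CCTGCACCTAGTTGACATCG	reverse	CB	Ca. Electrothrix reverse
CB836wR	CCTGCAYCTAGTTGACATCG	reverse	CB	Ca. Electrothrix reverse, wobble at position 7
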