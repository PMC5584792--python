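accession	name	consensus	max_mismatches
SYNTD001	synthetic transporter family core motif	DQSKEWNRGTDESKQNRWTG	9
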