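stimulatory_checkpoints	.	STIM01	STIM02	STIM03	STIM04	STIM05	STIM06	STIM07	STIM08	STIM09	STIM10	STIM11	STIM12	STIM13	STIM14	STIM15
inhibitory_checkpoints	.	INHIB01	INHIB02	INHIB03	INHIB04	INHIB05	INHIB06	INHIB07	INHIB08	INHIB09	INHIB10	INHIB11	INHIB12	INHIB13	INHIB14	INHIB15
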