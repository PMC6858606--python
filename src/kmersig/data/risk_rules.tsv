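label	gleason_min	gleason_max	stage_min	stage_max
HR	8	*	*	*
HR	*	*	T2c	*
LR	*	6	*	T2a
IR	*	*	*	*
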