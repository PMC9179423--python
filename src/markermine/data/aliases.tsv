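BCL-2	BCL2
MK167	MKI67
TFGBRII	TGFBR2
VEGF	VEGFA
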