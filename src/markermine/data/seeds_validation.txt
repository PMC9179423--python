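BAX
CDH1
CDKN1B
EGFR
ESR1
MK167
PLAU
TERT
TP53
VEGF
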