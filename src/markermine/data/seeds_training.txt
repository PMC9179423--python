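BAG1
BCL-2
CDKN1A
CXCR4
ERBB2
KRAS
PIK3CA
PTEN
TFGBRII
TYMS
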