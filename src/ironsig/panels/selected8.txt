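# Eight-gene iron signature selected by elastic-net Cox from the iron panel.
STEAP3
HFE
TMPRSS6
SFXN1
TFRC
UROS
SLC11A2
STEAP4
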