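# 16-gene iron regulatory gene signature (IRGS) panel.
# SYNTHETIC STAND-IN: the published IRGS membership is not bundled; this is a
# curated 16-gene iron-metabolism list of the right size, containing the
# signature genes this package's analyses refer to by name. Replace with the
# published list for real-data work.
HFE
TFRC
SFXN1
SLC25A37
STEAP3
TMPRSS6
UROS
SLC11A2
STEAP4
TFR2
SLC40A1
FTL
FTH1
ACO1
IREB2
HAMP
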