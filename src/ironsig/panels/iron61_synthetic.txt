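# 61-gene iron-metabolism candidate panel.
# SYNTHETIC STAND-IN: the published 61-gene list is not bundled; this is a
# curated iron-metabolism gene list of the right size (uptake, transport,
# storage, heme synthesis, Fe-S cluster assembly, hepcidin regulation),
# containing every gene this package's analyses refer to by name. Replace
# with the published list for real-data work.
STEAP3
HFE
TMPRSS6
SFXN1
TFRC
UROS
SLC11A2
STEAP4
TFR2
SLC25A37
FTL
FTH1
TF
LTF
CP
HEPH
HAMP
HFE2
SLC40A1
CYBRD1
ACO1
IREB2
STEAP1
STEAP2
FXN
ISCU
NFS1
GLRX5
ABCB7
ABCB10
ALAS1
ALAS2
FECH
HMOX1
HMOX2
BLVRA
BLVRB
SLC25A28
SLC39A14
SLC39A8
LCN2
SCARA5
FLVCR1
FLVCR2
SLC48A1
BMP6
NEO1
SMAD4
EPAS1
HIF1A
IL6
PCBP1
PCBP2
NCOA4
CIAO1
NUBP1
NUBP2
BOLA3
CISD1
CISD2
HSPA9
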