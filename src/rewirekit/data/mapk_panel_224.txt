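# 224-gene MAPK signaling panel (gene symbols, one per line)
PSMA5
PSMA3
PSMB3
PSMB5
PSMD3
JAK1
JAK3
PPP5C
SYNGAP1
ZBTB9
CALM2
APBB1IP
RASGRF1
RASGRF2
RAP1A
RAP1B
RAP2A
RAP2B
RAP2C
ARAF
BRAF
RAF1
HRAS
KRAS
NRAS
NF1
RASSF1
RASSF2
RASSF5
RGL1
RGL2
RGL3
NTF3
NTF4
NGF
BDNF
NTRK1
NTRK2
CCDC88A
CNKSR1
CNKSR2
RHEB
RHEBL1
RALA
RALB
UBE2K
MAPK1
MAPK3
MAPK4
MAPK6
MAPK7
MAPK8
MAPK9
MAPK10
MAPK11
MAPK12
MAPK13
MAPK14
MAP2K1
MAP2K2
MAP2K3
MAP2K4
MAP2K5
MAP2K6
MAP2K7
MAP3K1
MAP3K2
MAP3K3
MAP3K4
MAP3K5
MAP3K6
MAP3K7
MAP3K8
MAP3K9
MAP3K10
MAP3K11
MAP3K12
MAP3K13
MAP3K14
MAP4K1
MAP4K2
MAP4K3
MAP4K4
MAP4K5
MAPKAPK2
MAPKAPK3
MAPKAPK5
RPS6KA1
RPS6KA2
RPS6KA3
RPS6KA4
RPS6KA5
RPS6KA6
RPS6KB1
EGFR
FGFR1
FGFR2
FGFR3
FGFR4
FGF1
FGF2
FGF5
FGF7
FGF8
FGF9
FGF10
FGF14
PDGFRA
PDGFRB
PDGFA
PDGFB
TGFB1
TGFB2
TGFB3
TGFBR1
TGFBR2
TP53
MYC
JUN
JUNB
JUND
FOS
FOSB
ATF2
ATF4
ELK1
ELK4
SRF
MEF2C
GRB2
SOS1
SOS2
SHC1
PTPN5
PTPN7
PTPRR
DUSP1
DUSP2
DUSP3
DUSP4
DUSP5
DUSP6
DUSP7
DUSP8
DUSP9
DUSP10
DUSP14
DUSP16
AKT1
AKT2
AKT3
PIK3CA
RAC1
RAC2
RAC3
CDC42
PAK1
PAK2
RAPGEF2
RASGRP1
RASGRP2
RASGRP3
RASGRP4
RASA1
RASA2
HSPA1A
HSPA8
FLNA
FLNB
FLNC
CRK
CRKL
GNA12
GNG12
PRKCA
PRKCB
PRKCG
PRKACA
PRKACB
PLA2G4A
PPP3CA
PPP3CB
PPP3CC
PPP3R1
PPM1A
PPM1B
STMN1
MKNK1
MKNK2
EEF2K
STK3
STK4
TAOK1
TAOK2
TAOK3
GADD45A
GADD45B
GADD45G
DDIT3
NFKB1
NFKB2
RELA
RELB
IKBKB
CHUK
TRAF2
TRAF6
TNF
TNFRSF1A
IL1A
IL1B
IL1R1
FAS
FASLG
DAXX
ECSIT
TAB1
TAB2
NLK
MECOM
ARRB1
ARRB2
CACNA1C
CACNA1D
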