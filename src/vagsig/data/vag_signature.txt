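# VDAC1-associated gene signature (VAG): VDAC1 plus 44 interacting genes
# commonly dysregulated across six carcinomas (45 genes).
VDAC1
ACADVL
AGK
AP2M1
ATP6V1A
BCL2L1
CDK2
COX4I1
CYCS
DAP3
DBT
DENR
DHX30
ECI1
EIF6
FLAD1
GAPDH
GSN
GSTK1
HADHA
HAUS3
IGF2BP2
KIAA0391
KIF5B
LONP1
MAPK1
MCAT
MCL1
MDC1
MRPL3
MRPL9
MRPS10
MRPS17
MTERFD1
MTPAP
MUT
PANK2
PPID
RNGTT
TFB1M
TIAL1
TMX1
TOMM20
TUBA4A
YWHAB
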