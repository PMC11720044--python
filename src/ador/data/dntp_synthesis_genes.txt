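# De novo deoxyribonucleotide-synthesis gene symbols (curated pathway members:
# ribonucleotide reductase, thymidylate/purine/pyrimidine de novo synthesis,
# folate one-carbon supply). Used as the default gene set for the per-sample
# nucleotide-synthesis activity score.
RRM1
RRM2
RRM2B
TYMS
DTYMK
TK1
DCK
DCTD
DHFR
SHMT1
SHMT2
MTHFD1
MTHFD2
GART
PFAS
PAICS
ATIC
PPAT
ADSL
ADSS2
IMPDH1
IMPDH2
GMPS
CAD
DHODH
UMPS
CTPS1
NME1
NME2
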