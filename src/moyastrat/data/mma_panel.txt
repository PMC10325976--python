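# Synthetic stand-in candidate-gene panel for Moyamoya-associated genes.
# One HGNC symbol per line. Replace with a curated panel file for real use;
# the genes below are documented Moyamoya/arteriopathy-associated genes.
RNF213
NF1
ACTA2
GUCY1A3
JAG1
PCNT
STAT3
ANK1
SPTB
COL4A5
CASZ1
MTOR
SPRED1
NF2
FLNA
SAMHD1
CBL
PTPN11
HBB
MYH11
SMAD4
BRCC3
CNOT3
ELN
NOTCH1
NOTCH3
COL3A1
FBN1
TGFBR1
TGFBR2
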