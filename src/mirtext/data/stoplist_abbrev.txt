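PCR
DNA
RNA
HIV
AIDS
MRI
CT
ELISA
FACS
SDS
EDTA
ATP
ADP
GFP
PBS
DMSO
ANOVA
BMI
ICU
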