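IL	Interleukin
TNF	Tumor necrosis factor
IFN	Interferon
IGF	Insulin-like growth factor
EGF	Epidermal growth factor
FGF	Fibroblast growth factor
VEGF	Vascular endothelial growth factor
TGF	Transforming growth factor
BMP	Bone morphogenetic protein
HSP	Heat shock protein
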