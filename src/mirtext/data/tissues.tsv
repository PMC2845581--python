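cl0001	tissue	any	HeLa
cl0002	tissue	any	HEK293
cl0003	tissue	any	MCF-7
cl0004	tissue	any	HepG2
cl0005	tissue	any	A549
cl0006	tissue	any	Jurkat
cl0007	tissue	any	NIH3T3
ts0001	tissue	any	liver
ts0002	tissue	any	brain
ts0003	tissue	any	lung
ts0004	tissue	any	kidney
ts0005	tissue	any	heart
ts0006	tissue	any	spleen
ts0007	tissue	any	fibroblast
ts0008	tissue	any	lymphocyte
ts0009	tissue	any	hippocampus
ts0010	tissue	any	myocardium
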