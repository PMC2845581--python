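al
et al
Fig
Figs
Ref
Refs
Eq
Eqs
i.e
e.g
vs
cf
ca
approx
spp
sp
Dr
St
etc
resp
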