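physical_target	target
physical_target	targets
physical_target	targeted
physical_target	targeting
physical_target	bind
physical_target	binds
physical_target	binding
physical_target	bound
physical_target	interact
physical_target	interacts
physical_target	interaction
physical_target	interacting
physical_target	seed match
physical_target	base-pairs
physical_target	base pairing
repression	repress
repression	represses
repression	repressed
repression	repression
repression	suppress
repression	suppresses
repression	suppressed
repression	suppression
repression	inhibit
repression	inhibits
repression	inhibited
repression	inhibition
repression	downregulate
repression	downregulates
repression	downregulated
repression	downregulation
repression	down-regulates
repression	down-regulated
repression	down-regulation
repression	silences
repression	silenced
repression	silencing
repression	attenuates
repression	attenuated
repression	reduces
repression	reduced
co_expression	co-express
co_expression	co-expressed
co_expression	co-expression
co_expression	coexpressed
co_expression	coexpression
co_expression	correlate
co_expression	correlates
co_expression	correlated
co_expression	correlation
co_expression	inversely correlated
co_expression	co-regulated
co_expression	concordant expression
induction	induce
induction	induces
induction	induced
induction	induction
induction	upregulate
induction	upregulates
induction	upregulated
induction	upregulation
induction	up-regulates
induction	up-regulated
induction	up-regulation
induction	activate
induction	activates
induction	activated
induction	activation
induction	enhances
induction	enhanced
induction	stimulates
induction	stimulated
cleavage	cleave
cleavage	cleaves
cleavage	cleaved
cleavage	cleavage
cleavage	degrade
cleavage	degrades
cleavage	degraded
cleavage	degradation
cleavage	slicing
cleavage	sliced
cleavage	destabilizes
cleavage	destabilized
cleavage	destabilization
cleavage	mRNA decay
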