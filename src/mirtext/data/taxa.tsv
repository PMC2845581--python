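tax9606	taxon	hsa	human
tax9606	taxon	hsa	humans
tax9606	taxon	hsa	Homo sapiens
tax9606	taxon	hsa	H. sapiens
tax9606	taxon	hsa	patients
tax10090	taxon	mmu	mouse
tax10090	taxon	mmu	mice
tax10090	taxon	mmu	murine
tax10090	taxon	mmu	Mus musculus
tax10090	taxon	mmu	M. musculus
tax10116	taxon	rno	rat
tax10116	taxon	rno	rats
tax10116	taxon	rno	Rattus norvegicus
tax10116	taxon	rno	R. norvegicus
tax3702	taxon	ath	Arabidopsis thaliana
tax3702	taxon	ath	Arabidopsis
tax10376	taxon	ebv	Epstein-Barr virus
tax10376	taxon	ebv	EBV
tax6239	taxon	cel	Caenorhabditis elegans
tax6239	taxon	cel	C. elegans
tax7227	taxon	dme	Drosophila melanogaster
tax7227	taxon	dme	Drosophila
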