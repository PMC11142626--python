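# The 20 taxa of the NCBI gene2go GO annotation set, with clade classes
# used by the evolutionary-origin classifier.  Editable: classes are
# prokaryote | eukaryote (non-vertebrate) | vertebrate.
# taxon_id	clade	name
3702	eukaryote	Arabidopsis thaliana
4896	eukaryote	Schizosaccharomyces pombe
6239	eukaryote	Caenorhabditis elegans
7165	eukaryote	Anopheles gambiae
7227	eukaryote	Drosophila melanogaster
7955	vertebrate	Danio rerio
8364	vertebrate	Xenopus tropicalis
9031	vertebrate	Gallus gallus
9606	vertebrate	Homo sapiens
9615	vertebrate	Canis lupus familiaris
9823	vertebrate	Sus scrofa
9913	vertebrate	Bos taurus
10090	vertebrate	Mus musculus
10116	vertebrate	Rattus norvegicus
28985	eukaryote	Kluyveromyces lactis
33169	eukaryote	Eremothecium gossypii
214684	eukaryote	Cryptococcus neoformans
352472	eukaryote	Dictyostelium discoideum AX4
511145	prokaryote	Escherichia coli K-12 MG1655
559292	eukaryote	Saccharomyces cerevisiae S288C
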