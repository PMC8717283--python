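# Published Tas1r repertoire and umami/sweet predictions for 14 amphibians.
# Count entries "n(kPS)" mean n loci of which k are pseudogenes.
# umami/sweet columns are the published calls (1 = putative function).
species	binomial	order	Tas1r1	Tas1r2	Tas1r3	umami	sweet
Leishan spiny toad	Leptobrachium leishanense	Anura	1	1	0	0	0
Mexican spadefoot toad	Spea multiplicata	Anura	2	1	1	1	1
African bullfrog	Pyxicephalus adspersus	Anura	2	1	0	0	0
American bullfrog	Lithobates catesbeianus	Anura	2	0	0	0	0
Common frog	Rana temporaria	Anura	2(1PS)	2(1PS)	2	1	1
Tibetan Plateau frog	Nanorana parkeri	Anura	2	0	2(1PS)	1	0
Eastern banjo frog	Limnodynastes dumerilii	Anura	1	1	1	1	1
Strawberry poison frog	Oophaga pumilio	Anura	1	1	0	0	0
Asiatic toad	Bufo gargarizans	Anura	1	1	0	0	0
African clawed frog	Xenopus laevis	Anura	0	0	0	0	0
Western clawed frog	Xenopus tropicalis	Anura	0	0	0	0	0
Two-lined caecilian	Rhinatrema bivittatum	Gymnophiona	1	1	1	1	1
Gaboon caecilian	Geotrypetes seraphini	Gymnophiona	1	0	1	1	0
Tiny cayenne caecilian	Microcaecilia unicolor	Gymnophiona	1	1	2	1	1
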