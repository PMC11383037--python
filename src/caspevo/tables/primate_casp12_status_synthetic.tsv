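# SYNTHETIC status fixture: caspase-12 intact/pseudogene calls per species,
# constructed from the reported clade-level retention pattern (not a copy of
# any published per-species table). 1 = intact, 0 = pseudogene/lost.
species	CASP12
Human	0
Chimp	0
Gorilla	0
Orangutan	1
Gibbon	0
Macaque	1
Baboon	1
Colobus	1
Langur	1
Marmoset	0
Tamarin	0
SquirrelMonkey	0
Capuchin	0
OwlMonkey	0
Tarsier	1
Loris	1
Galago	0
Lemur	1
MouseLemur	1
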