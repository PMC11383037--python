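# SYNTHETIC status fixture: caspase-12 intact/pseudogene calls per species,
# constructed from the reported clade-level retention pattern (not a copy of
# any published per-species table). 1 = intact, 0 = pseudogene/lost.
species	Casp12
Mouse	1
SpretusMouse	1
CaroliMouse	1
WoodMouse	0
Rat	1
MountainRat	1
SpinyMouse	1
Gerbil	1
Jird	1
Hamster	0
DwarfHamster	1
Vole	0
PrairieVole	1
Lemming	1
Muskrat	1
Jerboa	0
Beaver	1
Squirrel	1
Marmot	0
Chipmunk	1
GuineaPig	0
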