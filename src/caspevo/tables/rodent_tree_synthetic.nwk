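(((((((Mouse,SpretusMouse),CaroliMouse),WoodMouse),((Rat,MountainRat),SpinyMouse)),(Gerbil,Jird)),(((Hamster,DwarfHamster),((Vole,PrairieVole),Lemming)),Muskrat)),((Jerboa,Beaver),((Squirrel,(Marmot,Chipmunk)),GuineaPig)));
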