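(((((((Human,Chimp),Gorilla),Orangutan),Gibbon),((Macaque,Baboon),(Colobus,Langur))),(((Marmoset,Tamarin),SquirrelMonkey),(Capuchin,OwlMonkey))),(Tarsier,((Loris,Galago),(Lemur,MouseLemur))));
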