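tag_id	pattern
filler.maa	surface=maa
filler.nanka	surface=nanka
filler.ano	surface=ano
filler.unto	surface=unto
filler.eeto	surface=eeto
filler.sono	surface=sono
filler.kono	surface=kono
filler.kou	surface=kou
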