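tag_id	pattern
auxsc.stative_01	surface=teiru
auxsc.compound_01	surface=hajimeru&pos=aux
auxben.benefactive_01	surface=kureru&pos=aux
auxben.benefactive_02	surface=ageru&pos=aux
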