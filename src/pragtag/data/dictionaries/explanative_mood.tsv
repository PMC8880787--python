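tag_id	pattern
expl.plain	surface=noda
expl.kedo	surface=nda;surface=kedo
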