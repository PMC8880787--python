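tag_id	pattern
cc.te_sequence	surface=te&pos=conj
cc.cond_resultative	surface=tara&pos=conj
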