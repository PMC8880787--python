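tag_id	pattern
lsr.ext_additive	surface=soshite
lsr.proj_quote	surface=to&pos=prt-quote
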