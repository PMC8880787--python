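tag_id	pattern
opt.optative	surface=tai&pos=aux
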