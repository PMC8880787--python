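tag_id	pattern
voice.passive_active	surface=sareru
voice.causative	surface=saseru
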