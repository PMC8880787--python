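tag_id	pattern
proc.material_doing	lemma=taberu
proc.mental_cognition	lemma=omou
proc.existential	lemma=iru&pos=verb
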