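tag_id	pattern
att.affect_emotion	lemma=ureshii
att.judgement_capacity	lemma=jouzu
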