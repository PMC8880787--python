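tag_id	pattern
modality.usuality	surface=suru;surface=koto;surface=aru
modality.ability	lemma=dekiru
modality.obligation	surface=nakereba;surface=naranai
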