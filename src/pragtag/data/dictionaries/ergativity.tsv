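tag_id	pattern
erg.middle	surface=oko
erg.middle	surface=koto;surface=aru
erg.effective	lemma=kowasu
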