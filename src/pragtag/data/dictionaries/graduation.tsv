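tag_id	pattern
grad.force_intensification	surface=totemo
grad.focus_softening	surface=chotto
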