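tag_id	pattern
negparticle.kana	surface=kana&pos=prt-final
negparticle.kane	surface=kane&pos=prt-final
negparticle.sa	surface=sa&pos=prt-final
negparticle.ne	surface=ne&pos=prt-final
negparticle.yo	surface=yo&pos=prt-final
negparticle.yona	surface=yona&pos=prt-final
negparticle.yone	surface=yone&pos=prt-final
negparticle.kane_nonfinal	surface=kane&pos=prt-mid
negparticle.sa_nonfinal	surface=sa&pos=prt-mid
negparticle.ne_nonfinal	surface=ne&pos=prt-mid
negparticle.yo_nonfinal	surface=yo&pos=prt-mid
negparticle.ne_other	surface=ne&pos=prt-other
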