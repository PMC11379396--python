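species,item,stage
rhesus,reckless,Low ICC
rhesus,sensitive,Low ICC
rhesus,unemotional,Low ICC
rhesus,vigilant,Low ICC
rhesus,eccentric,Low Communality
rhesus,tense,Low Communality
longtailed,excitable,Low ICC
longtailed,sensitive,Low ICC
longtailed,unpredictable,Low ICC
longtailed,eccentric,Low Communality
longtailed,intelligent,Low Communality
longtailed,vigilant,Low Communality
bonnet,fearful,Low ICC
bonnet,independent,Low ICC
bonnet,insecure,Low ICC
bonnet,sensitive,Low ICC
bonnet,tolerant,Low ICC
bonnet,vigilant,Low ICC
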