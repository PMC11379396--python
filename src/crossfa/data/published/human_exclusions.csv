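species,item,stage
rhesus,affiliative/companionable,Low ICC
rhesus,sensitive,Low ICC
rhesus,submissive/subordinate,Low ICC
rhesus,tense,Low ICC
rhesus,sociable,Low Communality
rhesus,solitary,Low Communality
longtailed,eccentric,Low Communality
longtailed,sensitive,Low Communality
bonnet,affiliative/companionable,Low ICC
bonnet,aggressive,Low ICC
bonnet,bold,Low ICC
bonnet,calm/equable,Low ICC
bonnet,eccentric,Low ICC
bonnet,equable,Low ICC
bonnet,excitable,Low ICC
bonnet,feisty,Low ICC
bonnet,gentle,Low ICC
bonnet,impulsive,Low ICC
bonnet,independent,Low ICC
bonnet,insecure,Low ICC
bonnet,intelligent,Low ICC
bonnet,irritable,Low ICC
bonnet,sensitive,Low ICC
bonnet,strong,Low ICC
bonnet,tolerant,Low ICC
bonnet,unemotional,Low ICC
bonnet,unpredictable,Low ICC
bonnet,vigilant,Low ICC
bonnet,understanding,Low Communality
bonnet,fearful,Low Communality
bonnet,sociable,Low MSA
bonnet,solitary,Low MSA
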