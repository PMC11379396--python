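item,Apprehensive,Exploratory,Irritable,Lazy
irritable,0.03,-0.04,0.89,0.08
aggressive,-0.27,0.09,0.84,0.14
excitable,0.20,0.28,0.66,-0.30
feisty,-0.22,0.02,0.84,0.05
bullying,-0.38,0.31,0.58,0.12
reckless,-0.10,0.52,0.46,-0.07
defiant,-0.19,0.54,0.48,0.01
unemotional,-0.44,0.01,-0.51,0.36
understanding,-0.24,0.10,-0.67,-0.11
tolerant,-0.12,0.69,-0.55,0.17
gentle,0.27,0.47,-0.59,0.19
calm/equable,-0.25,0.18,-0.76,0.23
equable,-0.23,0.23,-0.69,0.32
curious/exploratory/inquisitive,-0.16,0.78,-0.01,-0.17
vigilant,-0.13,0.37,0.18,-0.47
intelligent,-0.41,0.34,-0.08,-0.32
opportunistic,-0.25,0.65,0.06,-0.15
active/energetic,-0.08,0.72,0.08,-0.27
impulsive,0.05,0.54,0.52,-0.06
unpredictable,0.05,0.35,0.55,-0.26
persistent,-0.33,0.62,0.18,-0.01
confident,-0.75,0.31,0.07,-0.01
strong,-0.52,0.13,0.33,0.20
bold,-0.64,0.38,0.13,-0.07
effective,-0.59,0.42,0.18,0.09
direct/forceful/gets own way,-0.56,0.42,0.28,0.16
independent,-0.29,0.18,0.32,0.50
insecure,0.61,-0.02,-0.12,-0.32
cautious,0.74,-0.25,-0.10,0.00
timid,0.84,-0.10,-0.07,0.08
nervous/anxious/not calm,0.79,0.19,0.40,-0.13
fearful,0.89,-0.05,0.10,0.11
apprehensive,0.89,-0.02,0.08,0.15
lazy,0.27,-0.33,-0.09,0.61
slow,-0.06,-0.16,-0.22,0.72
depressed,0.64,0.02,0.22,0.51
submissive/subordinate,0.92,0.08,-0.11,-0.14
tense,0.44,-0.14,0.37,0.38
sociable,-0.01,0.84,-0.13,-0.05
affiliative/companionable,-0.03,0.72,-0.16,-0.03
solitary,0.32,-0.46,0.05,0.35
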