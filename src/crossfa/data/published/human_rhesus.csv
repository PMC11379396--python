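item,Irritable,Exploratory,Apprehensive,Lazy
irritable,0.92,-0.02,0.00,0.27
aggressive,0.82,0.11,0.08,0.17
excitable,0.81,0.20,-0.01,0.18
feisty,0.80,0.24,0.05,0.17
bullying,0.69,0.32,0.21,0.13
reckless,0.65,0.26,0.25,0.25
defiant,0.45,0.26,0.37,0.27
unemotional,-0.68,0.13,-0.13,0.29
understanding,-0.75,0.43,0.10,0.11
tolerant,-0.82,0.19,0.16,0.25
gentle,-0.83,-0.05,-0.01,0.27
calm/equable,-0.86,-0.02,0.07,0.29
equable,-0.93,0.18,0.06,0.20
curious/exploratory/inquisitive,-0.17,0.86,0.10,-0.09
vigilant,0.05,0.84,-0.20,-0.01
intelligent,-0.37,0.80,0.23,-0.05
opportunistic,-0.04,0.80,0.17,0.03
active/energetic,0.12,0.76,0.18,-0.21
impulsive,0.31,0.74,-0.10,-0.01
eccentric,0.15,0.67,-0.21,0.19
unpredictable,0.37,0.60,0.02,-0.04
persistent,0.28,0.47,0.25,0.27
confident,0.00,0.24,0.75,0.20
strong,-0.05,-0.05,0.72,0.32
bold,0.17,0.23,0.71,0.21
effective,0.27,0.26,0.60,0.30
direct/forceful/gets own way,0.37,0.32,0.51,0.28
independent,-0.05,0.40,0.47,0.22
insecure,0.14,-0.24,-0.61,0.19
cautious,0.04,-0.01,-0.65,0.26
timid,-0.12,-0.14,-0.69,0.38
nervous/anxious/not calm,0.21,0.40,-0.73,0.07
fearful,-0.01,0.05,-0.88,0.13
apprehensive,0.08,0.15,-0.91,0.17
lazy,-0.20,-0.48,-0.18,0.62
slow,-0.30,-0.28,-0.20,0.61
depressed,-0.17,-0.14,-0.41,0.43
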