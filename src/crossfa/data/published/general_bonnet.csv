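item,Confident,Active,Sociable,Equable
irritable,0.41,0.00,-0.06,0.66
bullying,0.81,-0.13,0.01,0.45
excitable,-0.16,0.70,0.04,0.47
jealous,0.66,-0.06,0.27,0.44
stingy/greedy,0.58,-0.12,0.16,0.18
feisty,0.64,0.19,-0.16,0.49
unpredictable,0.21,0.45,-0.49,0.33
aggressive,0.87,-0.13,-0.06,0.34
persistent,0.77,0.23,0.02,0.12
defiant,0.80,0.19,0.13,0.08
impulsive,0.25,0.57,-0.31,0.40
opportunistic,0.36,0.43,0.27,0.23
apprehensive,-0.52,-0.23,-0.35,0.37
nervous/anxious/not calm,-0.51,0.06,-0.22,0.62
submissive/subordinate,-0.87,0.16,-0.15,0.10
timid,-0.73,-0.23,-0.20,0.23
cautious,-0.78,-0.38,0.04,0.12
protective,0.77,-0.22,0.26,-0.09
intelligent,0.59,-0.01,0.24,-0.31
bold,0.74,0.42,-0.02,-0.11
direct/forceful/gets own way,0.92,-0.10,0.07,-0.01
confident,0.77,0.26,0.18,-0.21
strong,0.87,-0.06,-0.44,-0.15
effective,0.95,-0.10,0.03,0.03
sociable,0.24,0.23,0.76,0.03
affiliative/companionable,0.19,0.20,0.80,0.03
warm/affectionate,0.01,-0.10,0.81,-0.13
nurturant,-0.09,-0.18,0.80,-0.10
popular,0.58,0.14,0.50,-0.02
manipulative,0.72,-0.10,0.16,0.23
depressed,-0.20,-0.55,-0.52,0.01
solitary,-0.15,-0.15,-0.81,-0.14
lazy,-0.01,-0.78,-0.34,-0.08
slow,0.06,-0.80,-0.30,-0.14
curious/exploratory/inquisitive,0.18,0.87,-0.04,-0.16
active/energetic,0.00,0.85,0.15,0.06
equable,0.20,-0.08,0.04,-0.81
understanding,0.03,-0.24,0.59,-0.35
calm/equable,-0.02,-0.25,0.06,-0.68
playful,-0.30,0.95,-0.12,-0.14
gentle,-0.45,0.09,0.04,-0.65
reckless,0.44,0.62,-0.34,0.19
tense,-0.62,-0.26,-0.19,0.36
unemotional,-0.10,-0.34,-0.47,-0.40
eccentric,0.12,-0.06,-0.63,0.13
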