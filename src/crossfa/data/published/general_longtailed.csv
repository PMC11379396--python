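item,Confident,Sociable,Irritable/Equable,Active,Playful
irritable,-0.04,0.03,0.95,-0.12,0.04
bullying,0.36,0.05,0.66,0.10,0.24
jealous,0.33,0.22,0.54,0.06,0.32
stingy/greedy,0.58,-0.12,0.46,0.10,0.22
feisty,0.12,0.03,0.84,0.09,0.08
aggressive,0.40,0.10,0.70,0.07,0.23
persistent,0.24,0.13,0.26,0.48,0.35
defiant,0.14,0.15,0.37,0.38,0.21
impulsive,-0.05,-0.06,0.43,0.55,0.13
opportunistic,0.08,0.12,0.12,0.64,0.26
fearful,-0.83,-0.12,0.08,-0.15,0.02
apprehensive,-0.89,-0.05,0.04,-0.14,0.13
nervous/anxious/not calm,-0.74,-0.05,0.31,0.05,0.10
insecure,-0.75,0.44,0.21,-0.06,-0.04
submissive/subordinate,-0.96,-0.06,-0.05,0.15,0.01
timid,-0.83,-0.05,-0.01,-0.15,0.07
cautious,-0.81,-0.02,0.00,-0.20,0.04
protective,0.20,0.75,0.17,-0.04,0.20
bold,0.82,0.03,0.11,0.06,0.18
direct/forceful/gets own way,0.81,0.11,0.19,-0.02,0.21
confident,0.90,0.06,-0.01,0.01,0.11
strong,0.54,-0.04,0.14,0.10,0.46
effective,0.78,0.18,0.12,0.08,0.16
sociable,0.18,0.87,-0.03,0.08,-0.01
affiliative/companionable,0.20,0.82,-0.09,0.11,0.03
warm/affectionate,0.02,0.91,-0.10,0.00,0.06
nurturant,-0.18,0.91,-0.09,-0.03,0.11
popular,0.46,0.67,-0.03,-0.04,0.11
manipulative,0.11,0.31,0.31,0.25,0.34
independent,0.31,-0.80,-0.15,0.00,0.41
depressed,-0.62,-0.30,0.08,-0.32,0.30
solitary,-0.43,-0.75,-0.04,-0.04,0.26
lazy,-0.22,-0.10,0.01,-0.75,0.31
slow,0.17,0.13,-0.09,-0.79,0.29
curious/exploratory/inquisitive,0.08,0.05,-0.10,0.70,0.29
active/energetic,0.03,-0.09,-0.03,0.88,0.10
tolerant,-0.10,0.59,-0.54,0.08,0.25
equable,0.29,0.15,-0.76,-0.16,0.22
understanding,0.13,0.23,-0.64,0.09,0.03
calm/equable,0.27,0.14,-0.80,-0.15,0.17
playful,-0.15,0.24,-0.16,0.39,0.53
gentle,-0.28,0.50,-0.57,-0.06,0.25
reckless,-0.01,-0.02,0.25,0.54,0.21
tense,-0.27,-0.13,0.40,-0.55,0.10
unemotional,0.40,-0.10,-0.53,-0.26,0.26
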