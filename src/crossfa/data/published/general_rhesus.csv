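item,Irritable,Confident,Sociable,Active,Equable
irritable,0.84,-0.01,-0.06,-0.02,-0.22
bullying,0.79,-0.19,0.03,-0.06,-0.08
excitable,0.77,0.08,0.04,-0.15,-0.09
jealous,0.77,-0.13,0.18,0.00,-0.12
stingy/greedy,0.75,-0.13,0.05,0.14,-0.11
feisty,0.73,-0.06,0.11,-0.18,-0.15
unpredictable,0.70,0.31,-0.19,-0.27,0.12
aggressive,0.67,-0.30,-0.01,-0.05,-0.17
persistent,0.64,-0.21,0.15,-0.02,0.04
defiant,0.62,0.00,0.22,-0.17,0.01
impulsive,0.54,0.18,-0.19,-0.47,0.27
opportunistic,0.44,-0.13,0.19,-0.23,0.20
fearful,0.03,0.91,-0.02,0.09,0.06
apprehensive,0.08,0.91,0.11,0.10,0.02
nervous/anxious/not calm,0.34,0.85,0.04,-0.06,0.02
insecure,0.12,0.75,0.37,0.10,-0.12
submissive/subordinate,-0.14,0.70,-0.22,0.11,0.27
timid,-0.14,0.69,-0.03,0.26,0.17
cautious,-0.13,0.68,-0.09,0.20,0.18
protective,0.21,-0.53,0.38,0.15,0.24
intelligent,0.09,-0.54,0.18,-0.25,0.43
bold,0.54,-0.58,0.06,0.00,0.11
direct/forceful/gets own way,0.48,-0.63,0.15,0.06,0.04
confident,0.40,-0.66,0.13,-0.02,0.10
strong,0.29,-0.68,-0.22,0.14,0.33
effective,0.36,-0.72,0.19,0.13,0.03
sociable,0.18,0.00,0.89,0.06,0.07
affiliative/companionable,0.14,0.10,0.88,0.09,0.15
warm/affectionate,0.01,0.13,0.79,0.01,0.36
nurturant,-0.08,0.07,0.71,0.03,0.35
popular,0.11,-0.38,0.68,-0.08,0.11
manipulative,0.48,-0.01,0.54,-0.05,-0.17
independent,0.28,-0.43,-0.47,-0.05,0.39
depressed,0.12,0.26,-0.56,0.49,0.24
solitary,0.17,0.14,-0.72,0.13,0.45
lazy,0.06,0.10,-0.04,0.90,0.11
slow,-0.01,0.04,-0.04,0.86,0.16
curious/exploratory/inquisitive,0.04,0.00,0.01,-0.63,0.50
active/energetic,0.25,-0.05,-0.18,-0.78,0.18
tolerant,-0.30,0.10,0.30,0.11,0.65
equable,-0.34,-0.08,0.13,0.22,0.65
understanding,-0.19,-0.21,0.35,-0.03,0.65
calm/equable,-0.33,-0.09,0.13,0.35,0.61
playful,-0.18,0.10,0.11,-0.42,0.58
gentle,-0.41,0.12,0.32,0.15,0.57
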