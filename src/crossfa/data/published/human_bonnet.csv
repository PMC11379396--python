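item,Effective,Lazy/Exploratory,Apprehensive
bullying,0.78,0.15,-0.04
reckless,0.63,-0.36,0.28
defiant,0.79,-0.20,0.01
curious/exploratory/inquisitive,0.03,-0.87,-0.03
opportunistic,0.28,-0.56,0.05
active/energetic,0.10,-0.87,0.08
persistent,0.84,-0.10,0.11
confident,0.49,-0.26,-0.37
effective,0.95,0.06,0.06
direct/forceful/gets own way,0.89,0.12,-0.09
cautious,-0.52,0.34,0.27
timid,-0.68,0.20,0.23
nervous/anxious/not calm,0.00,-0.15,0.82
apprehensive,-0.13,0.30,0.67
lazy,0.04,0.89,0.04
slow,0.11,0.88,-0.02
depressed,-0.02,0.61,0.38
submissive/subordinate,-0.70,-0.16,0.39
tense,-0.31,0.22,0.55
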