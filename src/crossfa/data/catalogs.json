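{
  "general_items": [
    "irritable",
    "bullying",
    "excitable",
    "jealous",
    "stingy/greedy",
    "feisty",
    "unpredictable",
    "aggressive",
    "persistent",
    "defiant",
    "impulsive",
    "opportunistic",
    "fearful",
    "apprehensive",
    "nervous/anxious/not calm",
    "insecure",
    "submissive/subordinate",
    "timid",
    "cautious",
    "protective",
    "intelligent",
    "bold",
    "direct/forceful/gets own way",
    "confident",
    "strong",
    "effective",
    "sociable",
    "affiliative/companionable",
    "warm/affectionate",
    "nurturant",
    "popular",
    "manipulative",
    "independent",
    "depressed",
    "solitary",
    "lazy",
    "slow",
    "curious/exploratory/inquisitive",
    "active/energetic",
    "tolerant",
    "equable",
    "understanding",
    "calm/equable",
    "playful",
    "gentle",
    "reckless",
    "tense",
    "unemotional",
    "eccentric",
    "sensitive",
    "vigilant"
  ],
  "excluded_from_human": [
    "jealous",
    "manipulative",
    "nurturant",
    "playful",
    "popular",
    "protective",
    "stingy/greedy",
    "warm/affectionate"
  ]
}
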