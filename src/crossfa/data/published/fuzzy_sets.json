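{
  "general": {
    "species_order": ["rhesus", "longtailed", "bonnet"],
    "sets": {
      "Confident": {
        "rhesus": {"factor": "Confident", "reversed": true},
        "longtailed": {"factor": "Confident", "reversed": false},
        "bonnet": {"factor": "Confident", "reversed": false}
      },
      "Sociable": {
        "rhesus": {"factor": "Sociable", "reversed": false},
        "longtailed": {"factor": "Sociable", "reversed": false},
        "bonnet": {"factor": "Sociable", "reversed": false}
      },
      "Active": {
        "rhesus": {"factor": "Active", "reversed": true},
        "longtailed": {"factor": "Active", "reversed": false},
        "bonnet": {"factor": "Active", "reversed": false}
      },
      "Irritable": {
        "rhesus": {"factor": "Irritable", "reversed": false},
        "longtailed": {"factor": "Irritable/Equable", "reversed": false},
        "bonnet": {"factor": "Equable", "reversed": false}
      },
      "Equable": {
        "rhesus": {"factor": "Equable", "reversed": true},
        "longtailed": {"factor": "Irritable/Equable", "reversed": false},
        "bonnet": {"factor": "Equable", "reversed": false}
      }
    }
  },
  "human": {
    "species_order": ["rhesus", "longtailed", "bonnet"],
    "sets": {
      "Exploratory": {
        "rhesus": {"factor": "Exploratory", "reversed": false},
        "longtailed": {"factor": "Exploratory", "reversed": false},
        "bonnet": {"factor": "Lazy/Exploratory", "reversed": true}
      },
      "Apprehensive": {
        "rhesus": {"factor": "Apprehensive", "reversed": true},
        "longtailed": {"factor": "Apprehensive", "reversed": false},
        "bonnet": {"factor": "Apprehensive", "reversed": false}
      },
      "Lazy": {
        "rhesus": {"factor": "Lazy", "reversed": false},
        "longtailed": {"factor": "Lazy", "reversed": false},
        "bonnet": {"factor": "Lazy/Exploratory", "reversed": false}
      },
      "Irritable": {
        "rhesus": {"factor": "Irritable", "reversed": false},
        "longtailed": {"factor": "Irritable", "reversed": false}
      }
    }
  }
}
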