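{
  "name": "GLT1_simplified",
  "comment": "Simplified 3-state glial glutamate transporter cycle: free transporter binds glutamate, then either releases it back to the extracellular space or translocates it (removal from the extracellular pool). Rates follow the simplified GLT-1 kinetics used in hippocampal uptake models (binding ~1e7 /M/s, unbinding ~200 /s, translocation ~180 /s at room temperature); they are corrected to 36.5 C with Q10 = 3.",
  "t_ref_celsius": 23.0,
  "q10": 3.0,
  "states": ["T", "TG", "translocated"],
  "resting": "T",
  "open": [],
  "bound": ["TG"],
  "transitions": [
    {"from": "T", "to": "TG", "rate": 1.0e7, "ligand": true},
    {"from": "TG", "to": "T", "rate": 200.0, "ligand": false},
    {"from": "TG", "to": "translocated", "rate": 180.0, "ligand": false}
  ]
}
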