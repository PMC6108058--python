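{
  "name": "GluN_NMDA",
  "comment": "Five-state NMDA-receptor scheme (two sequential glutamate bindings with statistical factors, one desensitised state, one open state) with the rate constants of the classic cultured-hippocampal-neuron model. The slow glutamate unbinding gives the receptor its high steady-state affinity relative to AMPA receptors.",
  "t_ref_celsius": 23.0,
  "q10": 3.0,
  "states": [
    "C0",
    "C1",
    "C2",
    "D",
    "O"
  ],
  "resting": "C0",
  "open": [
    "O"
  ],
  "bound": [
    "C1",
    "C2",
    "D",
    "O"
  ],
  "transitions": [
    {
      "from": "C0",
      "to": "C1",
      "rate": 10000000.0,
      "ligand": true
    },
    {
      "from": "C1",
      "to": "C0",
      "rate": 82.0,
      "ligand": false
    },
    {
      "from": "C1",
      "to": "C2",
      "rate": 5000000.0,
      "ligand": true
    },
    {
      "from": "C2",
      "to": "C1",
      "rate": 164.0,
      "ligand": false
    },
    {
      "from": "C2",
      "to": "D",
      "rate": 8.4,
      "ligand": false
    },
    {
      "from": "D",
      "to": "C2",
      "rate": 1.8,
      "ligand": false
    },
    {
      "from": "C2",
      "to": "O",
      "rate": 46.5,
      "ligand": false
    },
    {
      "from": "O",
      "to": "C2",
      "rate": 91.6,
      "ligand": false
    }
  ]
}
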