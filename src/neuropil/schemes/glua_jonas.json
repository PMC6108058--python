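{
  "name": "GluA_AMPA",
  "comment": "Seven-state AMPA-receptor scheme (two sequential glutamate bindings, one open state, three desensitised states) with the rate constants of the classic hippocampal mossy-fibre patch model. Rates in /s or /M/s at the recording temperature (room temperature, ~23 C); all rates are Q10 = 3 corrected to 36.5 C at load.",
  "t_ref_celsius": 23.0,
  "q10": 3.0,
  "states": [
    "C0",
    "C1",
    "C2",
    "C3",
    "C4",
    "C5",
    "O"
  ],
  "resting": "C0",
  "open": [
    "O"
  ],
  "bound": [
    "C1",
    "C2",
    "C3",
    "C4",
    "C5",
    "O"
  ],
  "transitions": [
    {
      "from": "C0",
      "to": "C1",
      "rate": 4590000.0,
      "ligand": true
    },
    {
      "from": "C1",
      "to": "C0",
      "rate": 4260.0,
      "ligand": false
    },
    {
      "from": "C1",
      "to": "C2",
      "rate": 28400000.0,
      "ligand": true
    },
    {
      "from": "C2",
      "to": "C1",
      "rate": 3260.0,
      "ligand": false
    },
    {
      "from": "C2",
      "to": "O",
      "rate": 4240.0,
      "ligand": false
    },
    {
      "from": "O",
      "to": "C2",
      "rate": 900.0,
      "ligand": false
    },
    {
      "from": "C1",
      "to": "C3",
      "rate": 2890.0,
      "ligand": false
    },
    {
      "from": "C3",
      "to": "C1",
      "rate": 39.2,
      "ligand": false
    },
    {
      "from": "C3",
      "to": "C4",
      "rate": 1270000.0,
      "ligand": true
    },
    {
      "from": "C4",
      "to": "C3",
      "rate": 45.7,
      "ligand": false
    },
    {
      "from": "C2",
      "to": "C4",
      "rate": 172.0,
      "ligand": false
    },
    {
      "from": "C4",
      "to": "C2",
      "rate": 0.727,
      "ligand": false
    },
    {
      "from": "O",
      "to": "C5",
      "rate": 17.7,
      "ligand": false
    },
    {
      "from": "C5",
      "to": "O",
      "rate": 4.0,
      "ligand": false
    }
  ]
}
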