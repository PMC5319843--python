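{
  "name": "fig6a",
  "params": {"r1": 10, "r2": 100, "rs": 10000, "A": 1.001, "Kmax": 20},
  "capacity_mode": "bounded",
  "policy": {"mode": "fixed", "L1": 3, "L2": 3.083},
  "init": {"n1": 2, "n2": 2, "K": 5},
  "options": {"t_end": 10},
  "assumed": ["init"]
}
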