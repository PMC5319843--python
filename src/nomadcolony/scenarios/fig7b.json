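{
  "name": "fig7b",
  "params": {"r1": 10, "r2": 100, "rs": 10000, "A": 1.001, "Kmax": 7.5},
  "capacity_mode": "bounded",
  "policy": {"mode": "adaptive", "B": "auto"},
  "init": {"n1": 0, "n2": 2, "K": 5},
  "options": {"t_end": 10}
}
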