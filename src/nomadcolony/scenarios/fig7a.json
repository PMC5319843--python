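{
  "name": "fig7a",
  "params": {"r1": 1, "r2": 10, "rs": 1000, "A": 1.001, "Kmax": 20},
  "capacity_mode": "bounded",
  "policy": {"mode": "adaptive", "B": "auto"},
  "init": {"n1": 0, "n2": 2, "K": 5},
  "options": {"t_end": 100}
}
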