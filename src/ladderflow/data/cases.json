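{
  "case1": {"WP": 10, "WB": 10, "LD": 30, "LB": 90, "height": 10, "n_branches": 6},
  "case2": {"WP": 13, "WB": 10, "LD": 30, "LB": 90, "height": 10, "n_branches": 6},
  "case3": {"WP": 16, "WB": 10, "LD": 30, "LB": 90, "height": 10, "n_branches": 6},
  "case4": {"WP": 10, "WB": 10, "LD": 90, "LB": 270, "height": 10, "n_branches": 6},
  "case5": {"WP": 10, "WB": 10, "LD": 150, "LB": 450, "height": 10, "n_branches": 6}
}
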