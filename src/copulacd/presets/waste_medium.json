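{
 "regime": "medium",
 "discrete": {"B": 0.85, "F": 0.95, "W": 0.2857142857142857},
 "continuous": {
  "C":  {"intercept": 1.0, "parents": {"B": 1.0}, "noise_sd": 1.0},
  "E":  {"intercept": 0.5, "parents": {"F": 1.0, "W": 1.0}, "noise_sd": 1.0},
  "MW": {"intercept": 0.5, "parents": {"W": 1.0}, "noise_sd": 1.0},
  "D":  {"intercept": 0.0, "parents": {"B": 1.0, "W": 1.0, "E": 0.8}, "noise_sd": 1.0},
  "ME": {"intercept": 0.0, "parents": {"MW": 0.8, "D": 0.8}, "noise_sd": 1.0},
  "L":  {"intercept": 3.0, "parents": {"D": -0.8}, "noise_sd": 1.0}
 }
}
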