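{
 "regime": "high",
 "discrete": {"B": 0.85, "F": 0.95, "W": 0.2857142857142857},
 "continuous": {
  "C":  {"intercept": 1.0, "parents": {"B": 2.0}, "noise_sd": 0.3},
  "E":  {"intercept": 0.5, "parents": {"F": 1.0, "W": 1.0}, "noise_sd": 0.3},
  "MW": {"intercept": 0.5, "parents": {"W": 1.0}, "noise_sd": 0.3},
  "D":  {"intercept": 0.0, "parents": {"B": 1.0, "W": 1.0, "E": 1.0}, "noise_sd": 0.12},
  "ME": {"intercept": 0.0, "parents": {"MW": 1.0, "D": 1.0}, "noise_sd": 0.12},
  "L":  {"intercept": 3.0, "parents": {"D": -1.0}, "noise_sd": 0.12}
 }
}
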