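{
  "description": "Echo-vs-FP difference statistics in healthy subjects (literature reference) and the printed 95% ranges (mean +/- half_width, ms).",
  "events": {
    "MC": {"mean": 4,  "sd": 11, "n": 41, "printed_half_width": 22},
    "AO": {"mean": -3, "sd": 11, "n": 39, "printed_half_width": 22},
    "AC": {"mean": -5, "sd": 12, "n": 39, "printed_half_width": 23},
    "MO": {"mean": -7, "sd": 19, "n": 39, "printed_half_width": 37}
  }
}
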