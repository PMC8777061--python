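{
  "schema_version": "1.0",
  "red": {
    "state1": {"mean": 1000.0, "sd": 150.0, "weight": 0.5},
    "state2": {"mean": 5000.0, "sd": 900.0, "weight": 0.5}
  },
  "green": {
    "state1": {"mean": 1000.0, "sd": 150.0, "weight": 0.5},
    "state2": {"mean": 5000.0, "sd": 900.0, "weight": 0.5}
  },
  "n_samples": 0,
  "probe_counts": {},
  "provenance": "synthetic hand-written reference for tests"
}
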