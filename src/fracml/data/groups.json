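{
  "version": 1,
  "2d": {
    "i": {
      "C": 20.0, "WCa": 4.0, "WK": 8.0, "WL": 2.0,
      "FCa": 120.0, "FK": -84.0, "FL": -60.0,
      "F1": -1.2, "F2": 18.0, "F3": 12.0, "F4": 17.4,
      "phi": 0.067,
      "applied_currents": [40.0, 45.0]
    },
    "ii": {
      "C": 20.0, "WCa": 4.4, "WK": 8.0, "WL": 2.0,
      "FCa": 120.0, "FK": -84.0, "FL": -60.0,
      "F1": -1.2, "F2": 18.0, "F3": 2.0, "F4": 30.0,
      "phi": 0.04,
      "applied_currents": [100.0]
    }
  },
  "3d": {
    "i": {
      "WCa": 0.9, "WK": 2.0, "WL": 0.5,
      "FCa": 1.0, "FK": -0.7, "FL": -0.5,
      "F1": -0.01, "F2": 0.15, "F4": 0.04,
      "phi": 0.033, "F0": 0.22, "theta": 0.003,
      "applied_currents": []
    },
    "ii": {
      "WCa": 1.36, "WK": 2.0, "WL": 0.5,
      "FCa": 1.0, "FK": -0.7, "FL": -0.5,
      "F1": -0.01, "F2": 0.15, "F4": 0.16,
      "phi": 0.033, "F0": 0.1, "theta": 0.003,
      "applied_currents": []
    },
    "iii": {
      "WCa": 0.9, "WK": 2.0, "WL": 0.5,
      "FCa": 1.0, "FK": -0.7, "FL": -0.5,
      "F1": -0.01, "F2": 0.15, "F4": 0.05,
      "phi": 0.033, "F0": 0.0, "theta": 0.005,
      "applied_currents": []
    }
  }
}
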