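{
  "n_pregabalin": 31,
  "n_placebo": 29,
  "responder_rate_pregabalin": 0.5161290322580645,
  "responder_rate_placebo": 0.41379310344827586,
  "diary_baseline": {"median": 4.0, "q1": 2.4, "q3": 5.4},
  "responder_reduction_range": [35.0, 75.0],
  "nonresponder_reduction_range": [-25.0, 25.0],
  "missing_diary_fraction": 0.0,
  "seed": 0,
  "feature_calibration": {
    "pregabalin": {
      "responder": {
        "ppdt_control": {"median": 269, "q1": 213, "q3": 329},
        "ppdt_ratio": {"median": 0.7, "q1": 0.5, "q3": 1.0},
        "epdt_control": {"median": 3.7, "q1": 2.7, "q3": 5.1},
        "epdt_ratio": {"median": 1.2, "q1": 0.9, "q3": 1.3},
        "cold_pressor": {"median": 27, "q1": 18, "q3": 56},
        "cpm": {"median": 4, "q1": -17, "q3": 19},
        "pptt_pre": {"median": 500, "q1": 350, "q3": 700}
      },
      "nonresponder": {
        "ppdt_control": {"median": 175, "q1": 120, "q3": 329},
        "ppdt_ratio": {"median": 0.7, "q1": 0.6, "q3": 1.0},
        "epdt_control": {"median": 2.7, "q1": 2.2, "q3": 5.6},
        "epdt_ratio": {"median": 1.6, "q1": 1.5, "q3": 2.0},
        "cold_pressor": {"median": 43, "q1": 25, "q3": 57},
        "cpm": {"median": 0, "q1": 0, "q3": 4},
        "pptt_pre": {"median": 500, "q1": 350, "q3": 700}
      }
    },
    "placebo": {
      "responder": {
        "ppdt_control": {"median": 338, "q1": 125, "q3": 458},
        "ppdt_ratio": {"median": 0.7, "q1": 0.5, "q3": 0.8},
        "epdt_control": {"median": 3.9, "q1": 2.9, "q3": 5.0},
        "epdt_ratio": {"median": 1.3, "q1": 1.0, "q3": 1.7},
        "cold_pressor": {"median": 88, "q1": 25, "q3": 180},
        "cpm": {"median": 16, "q1": 2, "q3": 34},
        "pptt_pre": {"median": 500, "q1": 350, "q3": 700}
      },
      "nonresponder": {
        "ppdt_control": {"median": 132, "q1": 97, "q3": 341},
        "ppdt_ratio": {"median": 0.8, "q1": 0.4, "q3": 1.3},
        "epdt_control": {"median": 4.7, "q1": 2.0, "q3": 6.2},
        "epdt_ratio": {"median": 1.3, "q1": 1.0, "q3": 1.3},
        "cold_pressor": {"median": 29, "q1": 20, "q3": 46},
        "cpm": {"median": 10, "q1": 0, "q3": 30},
        "pptt_pre": {"median": 500, "q1": 350, "q3": 700}
      }
    }
  }
}
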