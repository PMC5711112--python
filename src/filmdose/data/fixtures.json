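{
  "schema": "filmdose-fixtures-1",
  "description": "Synthetic RANDO-phantom dose-map fixtures. surface [mean cGy, SE cGy] per aspect and profile_peak_cgy are the reference per-acquisition endpoints the generator programs; shape parameters encode the qualitative profile structure (source above the patient loads the anterior side, posterior tube arc loads the posterior, helical MV acquisition is near-uniform) and the treatment-position isocenter offset that skews lateral profiles.",
  "fixtures": {
    "OBI_21eX": {
      "head":   {"surface": {"Ant": [0.05, 0.01], "Post": [0.50, 0.01], "Left": [0.38, 0.01], "Right": [0.44, 0.01]}, "profile_peak_cgy": 0.50, "vertical_peak_mm": -6.0, "lateral_offset_mm": 5.0},
      "thorax": {"surface": {"Ant": [0.75, 0.01], "Post": [0.64, 0.01], "Left": [0.58, 0.01], "Right": [0.65, 0.01]}, "profile_peak_cgy": 1.01, "vertical_peak_mm": 0.0, "lateral_offset_mm": 5.0},
      "pelvis": {"surface": {"Ant": [3.72, 0.06], "Post": [3.48, 0.05], "Left": [2.74, 0.04], "Right": [2.58, 0.04]}, "profile_peak_cgy": 4.91, "vertical_peak_mm": 0.0, "lateral_offset_mm": 5.0}
    },
    "OBI_TrueBeam": {
      "head":   {"surface": {"Ant": [0.09, 0.01], "Post": [0.27, 0.01], "Left": [0.32, 0.01], "Right": [0.31, 0.01]}, "profile_peak_cgy": 0.38, "vertical_peak_mm": -6.0, "lateral_offset_mm": 5.0},
      "thorax": {"surface": {"Ant": [0.65, 0.01], "Post": [0.48, 0.01], "Left": [0.47, 0.01], "Right": [0.51, 0.01]}, "profile_peak_cgy": 0.84, "vertical_peak_mm": 0.0, "lateral_offset_mm": 5.0},
      "pelvis": {"surface": {"Ant": [3.10, 0.05], "Post": [2.02, 0.03], "Left": [1.89, 0.03], "Right": [2.02, 0.03]}, "profile_peak_cgy": 3.15, "vertical_peak_mm": 0.0, "lateral_offset_mm": 5.0}
    },
    "CyberKnife": {
      "head":   {"surface": {"Ant": [4.33, 0.07], "Post": [0.50, 0.01], "Left": [2.27, 0.04], "Right": [2.09, 0.04]}, "profile_peak_cgy": 4.33, "vertical_peak_mm": 6.0, "lateral_offset_mm": 0.0},
      "thorax": {"surface": {"Ant": [3.86, 0.06], "Post": [0.45, 0.01], "Left": [1.75, 0.03], "Right": [1.74, 0.03]}, "profile_peak_cgy": 3.86, "vertical_peak_mm": 6.0, "lateral_offset_mm": 0.0},
      "pelvis": {"surface": {"Ant": [6.50, 0.10], "Post": [0.30, 0.01], "Left": [3.30, 0.05], "Right": [3.25, 0.05]}, "profile_peak_cgy": 6.50, "vertical_peak_mm": 6.0, "lateral_offset_mm": 0.0}
    },
    "TomoTherapy": {
      "head":   {"surface": {"Ant": [2.07, 0.03], "Post": [2.92, 0.05], "Left": [2.22, 0.04], "Right": [2.31, 0.04]}, "profile_peak_cgy": 3.84, "vertical_peak_mm": -3.0, "lateral_offset_mm": 5.0},
      "thorax": {"surface": {"Ant": [1.05, 0.02], "Post": [1.70, 0.03], "Left": [0.97, 0.02], "Right": [0.89, 0.02]}, "profile_peak_cgy": 1.90, "vertical_peak_mm": -3.0, "lateral_offset_mm": 5.0},
      "pelvis": {"surface": {"Ant": [0.98, 0.02], "Post": [1.49, 0.03], "Left": [0.79, 0.02], "Right": [0.71, 0.02]}, "profile_peak_cgy": 2.09, "vertical_peak_mm": -3.0, "lateral_offset_mm": 5.0}
    }
  }
}
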