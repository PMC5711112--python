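{
  "schema": "filmdose-muen-ratio-1",
  "description": "Spectrum-averaged water-to-air mass-energy-absorption-coefficient ratios, free in air, indexed by first half-value layer in mm Al (TG-61 in-air method). Linear interpolation between nodes.",
  "hvl_mm_al": [2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 10.0],
  "ratio_water_air": [1.031, 1.037, 1.043, 1.047, 1.051, 1.054, 1.057, 1.061]
}
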