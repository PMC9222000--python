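{
  "intercept": 1331.50420234964,
  "coefficients": {
    "radius_min": 5.95568628644,
    "fractal_dimension": -1479.27930311731,
    "gray_min": 0.40274897061,
    "gray_max": 0.53105523026,
    "margination": 275.38324653827,
    "gray_green": -0.89343166330,
    "gray_blue": 0.51289341737
  },
  "cutoff": -1.1134,
  "orientation": "higher_score_is_high_grade",
  "provenance": "published 7-variable discriminant for Gleason <=3 vs >=4"
}
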