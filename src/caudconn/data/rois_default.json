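[
  {"name": "caudate_seed", "network": "seed", "center_mm": [12, 10, 8], "radius_mm": 6.0, "bilateral": true},
  {"name": "fpn_lateral_pfc", "network": "FPN", "center_mm": [41, 55, 4], "radius_mm": 6.0, "bilateral": true},
  {"name": "fpn_medial_pfc", "network": "FPN", "center_mm": [5, 22, 47], "radius_mm": 6.0, "bilateral": true},
  {"name": "fpn_anterior_parietal", "network": "FPN", "center_mm": [52, -50, 49], "radius_mm": 6.0, "bilateral": true},
  {"name": "dmn_medial_pfc", "network": "DMN", "center_mm": [7, 46, -2], "radius_mm": 6.0, "bilateral": true},
  {"name": "dmn_posterior_parietal", "network": "DMN", "center_mm": [42, -61, 31], "radius_mm": 6.0, "bilateral": true},
  {"name": "dmn_precuneus", "network": "DMN", "center_mm": [3, -49, 25], "radius_mm": 6.0, "bilateral": true},
  {"name": "caudate_dmn_seed", "network": "seed", "center_mm": [8, 10, 1], "radius_mm": 6.0, "bilateral": true}
]
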