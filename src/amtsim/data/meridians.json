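{
  "meridians": [
    {"code": "LU", "name": "Lung Meridian of Hand-Taiyin", "organ": "lung", "n_points": 11},
    {"code": "LI", "name": "Large Intestine Meridian of Hand-Yangming", "organ": "large_intestine", "n_points": 20},
    {"code": "ST", "name": "Stomach Meridian of Foot-Yangming", "organ": "stomach", "n_points": 45},
    {"code": "SP", "name": "Spleen Meridian of Foot-Taiyin", "organ": "spleen", "n_points": 21},
    {"code": "HT", "name": "Heart Meridian of Hand-Shaoyin", "organ": "heart", "n_points": 9},
    {"code": "SI", "name": "Small Intestine Meridian of Hand-Taiyang", "organ": "small_intestine", "n_points": 19},
    {"code": "BL", "name": "Bladder Meridian of Foot-Taiyang", "organ": "bladder", "n_points": 67},
    {"code": "KI", "name": "Kidney Meridian of Foot-Shaoyin", "organ": "kidney", "n_points": 27},
    {"code": "PC", "name": "Pericardium Meridian of Hand-Jueyin", "organ": "pericardium", "n_points": 9},
    {"code": "TE", "name": "Triple Energizer Meridian of Hand-Shaoyang", "organ": "triple_energizer", "n_points": 23},
    {"code": "GB", "name": "Gallbladder Meridian of Foot-Shaoyang", "organ": "gallbladder", "n_points": 44},
    {"code": "LR", "name": "Liver Meridian of Foot-Jueyin", "organ": "liver", "n_points": 14},
    {"code": "CV", "name": "Conception Vessel Meridian", "organ": null, "n_points": 24},
    {"code": "GV", "name": "Governor Vessel Meridian", "organ": null, "n_points": 28},
    {"code": "EX", "name": "Extra points", "organ": null, "n_points": 48,
     "subseries": {"HN": 15, "CA": 1, "B": 9, "UE": 11, "LE": 12}}
  ]
}
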