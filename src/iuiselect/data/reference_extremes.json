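{
  "discovery": {
    "male_age": {"no_pregnancy": [26.0, 44.0], "pregnancy": [26.0, 41.0]},
    "ejaculate_volume": {"no_pregnancy": [0.5, 8.0], "pregnancy": [1.5, 7.5]},
    "ejaculate_concentration": {"no_pregnancy": [4.0, 439.0], "pregnancy": [10.36, 243.99]},
    "ejaculate_total_count": {"no_pregnancy": [12.5, 1223.0], "pregnancy": [51.79, 1105.34]},
    "ejaculate_progressive_motility": {"no_pregnancy": [5.0, 86.0], "pregnancy": [18.0, 74.0]},
    "ejaculate_immotile": {"no_pregnancy": [1.0, 86.0], "pregnancy": [2.0, 62.0]},
    "ejaculate_total_motile": {"no_pregnancy": [2.5, 819.0], "pregnancy": [14.5, 722.21]},
    "ejaculate_morphology": {"no_pregnancy": [1.0, 18.0], "pregnancy": [2.0, 15.0]},
    "ejaculate_alkaline_comet": {"no_pregnancy": [22.0, 82.0], "pregnancy": [25.0, 72.0]},
    "ejaculate_neutral_comet": {"no_pregnancy": [23.0, 90.0], "pregnancy": [33.0, 90.0]},
    "swimup_concentration": {"no_pregnancy": [1.19, 267.0], "pregnancy": [9.68, 395.95]},
    "swimup_total_count": {"no_pregnancy": [0.48, 106.9], "pregnancy": [3.87, 158.38]},
    "swimup_progressive_motility": {"no_pregnancy": [10.0, 98.0], "pregnancy": [38.0, 93.0]},
    "swimup_immotile": {"no_pregnancy": [0.0, 81.0], "pregnancy": [1.0, 45.0]},
    "swimup_total_motile": {"no_pregnancy": [0.26, 90.6], "pregnancy": [1.68, 125.12]},
    "swimup_alkaline_comet": {"no_pregnancy": [20.0, 75.0], "pregnancy": [22.0, 59.0]},
    "swimup_neutral_comet": {"no_pregnancy": [17.0, 91.0], "pregnancy": [26.0, 82.0]},
    "female_age": {"no_pregnancy": [21.0, 39.0], "pregnancy": [24.0, 38.0]},
    "female_bmi": {"no_pregnancy": [18.0, 45.0], "pregnancy": [18.0, 40.0]},
    "infertility_duration": {"no_pregnancy": [5.0, 120.0], "pregnancy": [6.0, 48.0]},
    "fsh": {"no_pregnancy": [2.59, 10.8], "pregnancy": [4.47, 11.4]},
    "lh": {"no_pregnancy": [2.22, 27.28], "pregnancy": [2.58, 17.81]},
    "estradiol": {"no_pregnancy": [10.0, 450.0], "pregnancy": [21.0, 87.4]},
    "prolactin": {"no_pregnancy": [4.76, 58.0], "pregnancy": [4.76, 42.57]},
    "antral_follicle_count": {"no_pregnancy": [3.0, 27.0], "pregnancy": [6.0, 30.0]}
  },
  "validation": {
    "male_age": {"no_pregnancy": [26.0, 44.0], "pregnancy": [25.0, 41.0]},
    "ejaculate_volume": {"no_pregnancy": [0.5, 8.0], "pregnancy": [1.6, 7.3]},
    "ejaculate_concentration": {"no_pregnancy": [4.0, 439.0], "pregnancy": [14.26, 270.65]},
    "ejaculate_total_count": {"no_pregnancy": [12.5, 1223.0], "pregnancy": [68.5, 984.0]},
    "ejaculate_progressive_motility": {"no_pregnancy": [5.0, 86.0], "pregnancy": [6.0, 79.0]},
    "ejaculate_immotile": {"no_pregnancy": [1.0, 86.0], "pregnancy": [2.0, 75.0]},
    "ejaculate_total_motile": {"no_pregnancy": [2.5, 819.0], "pregnancy": [8.2, 777.0]},
    "ejaculate_morphology": {"no_pregnancy": [1.0, 18.0], "pregnancy": [0.0, 6.0]},
    "ejaculate_alkaline_comet": {"no_pregnancy": [22.0, 82.0], "pregnancy": [25.0, 67.0]},
    "ejaculate_neutral_comet": {"no_pregnancy": [23.0, 90.0], "pregnancy": [20.0, 91.0]},
    "swimup_concentration": {"no_pregnancy": [1.19, 267.0], "pregnancy": [9.17, 263.18]},
    "swimup_total_count": {"no_pregnancy": [0.48, 106.9], "pregnancy": [3.67, 105.27]},
    "swimup_progressive_motility": {"no_pregnancy": [10.0, 98.0], "pregnancy": [36.0, 94.0]},
    "swimup_immotile": {"no_pregnancy": [0.0, 81.0], "pregnancy": [1.0, 40.0]},
    "swimup_total_motile": {"no_pregnancy": [0.26, 90.6], "pregnancy": [1.72, 76.0]},
    "swimup_alkaline_comet": {"no_pregnancy": [20.0, 75.0], "pregnancy": [21.0, 54.0]},
    "swimup_neutral_comet": {"no_pregnancy": [17.0, 91.0], "pregnancy": [22.0, 65.0]},
    "female_age": {"no_pregnancy": [23.0, 40.0], "pregnancy": [26.0, 39.0]},
    "female_bmi": {"no_pregnancy": [17.24, 45.0], "pregnancy": [17.24, 35.7]},
    "infertility_duration": {"no_pregnancy": [6.0, 84.0], "pregnancy": [12.0, 48.0]},
    "fsh": {"no_pregnancy": [1.58, 10.49], "pregnancy": [1.58, 11.4]},
    "lh": {"no_pregnancy": [0.54, 26.72], "pregnancy": [0.54, 18.63]},
    "estradiol": {"no_pregnancy": [6.0, 384.0], "pregnancy": [8.0, 85.0]},
    "prolactin": {"no_pregnancy": [3.18, 77.82], "pregnancy": [4.32, 77.82]},
    "antral_follicle_count": {"no_pregnancy": [4.0, 26.0], "pregnancy": [4.0, 25.0]}
  }
}
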