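{
  "comment": "Melanoma-suspicious CIELab colors. Channel order is [L, a, b]. Range colors list [min, max] corner pairs; reference colors list a single CIELab point matched by Minkowski distance.",
  "ranges": {
    "black": [[0.06, 0.27, 0.10], [39.91, 30.23, 22.10]],
    "dark_brown": [[14.32, 6.85, 6.96], [47.57, 27.14, 46.81]],
    "light_brown": [[47.94, 11.89, 19.86], [71.65, 44.81, 64.78]]
  },
  "references": {
    "white": [100.0, 0.0, 0.0],
    "red": [54.29, 80.81, 69.89],
    "blue_gray": [50.28, -30.14, -11.96]
  }
}
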