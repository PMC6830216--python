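{
  "comment": "Single-Gaussian per-element scattering kernel: amplitude proportional to atomic number, sigma in Angstrom. Unknown elements fall back to carbon. Replace with a multi-Gaussian table if higher spectral fidelity is needed.",
  "fallback": "C",
  "elements": {
    "H": {
      "amplitude": 1.0,
      "sigma": 0.45
    },
    "C": {
      "amplitude": 6.0,
      "sigma": 0.6
    },
    "N": {
      "amplitude": 7.0,
      "sigma": 0.6
    },
    "O": {
      "amplitude": 8.0,
      "sigma": 0.6
    },
    "P": {
      "amplitude": 15.0,
      "sigma": 0.7
    },
    "S": {
      "amplitude": 16.0,
      "sigma": 0.7
    },
    "Fe": {
      "amplitude": 26.0,
      "sigma": 0.75
    },
    "Mg": {
      "amplitude": 12.0,
      "sigma": 0.7
    },
    "Zn": {
      "amplitude": 30.0,
      "sigma": 0.75
    },
    "Ca": {
      "amplitude": 20.0,
      "sigma": 0.75
    }
  }
}
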