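{
  "format_version": 1,
  "comment": "Standard four-Gaussian Muller-Brown surface parameters; energies treated as kJ/mol, coordinates as Angstrom.",
  "A": [-200.0, -100.0, -170.0, 15.0],
  "a": [-1.0, -1.0, -6.5, 0.7],
  "b": [0.0, 0.0, 11.0, 0.6],
  "c": [-10.0, -10.0, -6.5, 0.7],
  "x0": [1.0, 0.0, -0.5, -1.0],
  "y0": [0.0, 0.5, 1.5, 1.0]
}
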