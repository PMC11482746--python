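{
  "_comment": "Reference model-compound (random-coil) pKa values for titratable groups, as tabulated from pentapeptide NMR measurements (Platzer et al., J. Biomol. NMR, 2014). 'nt'/'ct' are the alpha-amino and alpha-carboxyl termini. These are data, not code, and may be overridden.",
  "D": 3.86,
  "E": 4.34,
  "H": 6.45,
  "C": 8.49,
  "Y": 9.76,
  "K": 10.34,
  "nt": 8.23,
  "ct": 3.55
}
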