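{
  "_comment": "Common modified/non-standard residues mapped to their canonical parent (3-letter codes). Residues absent from this table raise NonCanonicalResidueError instead of being modelled silently.",
  "MSE": "MET",
  "SEP": "SER",
  "TPO": "THR",
  "PTR": "TYR",
  "CSO": "CYS",
  "CME": "CYS",
  "OCS": "CYS",
  "KCX": "LYS",
  "MLY": "LYS",
  "M3L": "LYS",
  "ALY": "LYS",
  "HYP": "PRO",
  "FME": "MET",
  "CSD": "CYS",
  "LLP": "LYS"
}
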