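{
  "_comment": "Synthetic stand-in signature set for detecting HLA-DM chaperone chains by exact substring match. The curated DM alpha/beta reference sequences must be supplied by the user for real data; these synthetic marker motifs (improbable in natural sequences) exist so the exclusion machinery is exercised end-to-end by the test fixtures.",
  "alpha": ["WCWHWMWDWAWCWHWAW"],
  "beta": ["WCWHWMWDWEWCWHWEW"]
}
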