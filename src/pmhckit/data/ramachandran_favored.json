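{
  "_comment": "Backbone (phi, psi) pairs in degrees sampled when building flank residues de novo: beta/extended, polyproline-II and alpha regions of the Ramachandran-favored area.",
  "torsions": [
    [-139.0, 135.0], [-120.0, 130.0], [-135.0, 150.0], [-100.0, 120.0],
    [-75.0, 145.0], [-65.0, 140.0],
    [-57.0, -47.0], [-63.0, -42.0], [-70.0, -35.0],
    [-87.0, 2.0], [-120.0, 80.0], [-150.0, 155.0]
  ]
}
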