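{
  "_comment": "CLIP (class-II-associated invariant-chain peptide) sequences; a template candidate whose peptide contains any of these as a substring is excluded from the template set. Defaults cover the canonical human CLIP(87-101) and its 9-mer binding core.",
  "cores": ["MRMATPLLM", "PVSKMRMATPLLMQA"]
}
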