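# Drosophila histone tail definitions (residue ranges, inclusive, 1-based).
name: drosophila
tails:
  H3:
    - {tag: H3, range: [1, 45]}
  H4:
    - {tag: H4, range: [1, 32]}
  H2A:
    - {tag: H2AN, range: [1, 17]}
    - {tag: H2AC, range: [115, 124]}
  H2B:
    - {tag: H2B, range: [1, 31]}
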