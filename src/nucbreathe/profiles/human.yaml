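# Human histone tail definitions (residue ranges, inclusive, 1-based).
# The histone core is the complement of these ranges.
# Note on hH2A: the C-terminal exclusion is printed in the source annotation
# as "1-18 and 129"; the default C-tail here is 119-129 (by analogy with the
# Drosophila H2A C-tail 115-124). Override per-chain if a different C-tail
# start is wanted.
name: human
tails:
  H3:
    - {tag: H3, range: [1, 45]}
  H4:
    - {tag: H4, range: [1, 32]}
  H2A:
    - {tag: H2AN, range: [1, 18]}
    - {tag: H2AC, range: [119, 129]}
  H2B:
    - {tag: H2B, range: [1, 33]}
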