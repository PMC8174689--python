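# Tail-less nucleosome: no tail residues; the whole histone is "core".
name: tailless
tails:
  H3: []
  H4: []
  H2A: []
  H2B: []
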