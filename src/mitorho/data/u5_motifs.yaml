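# Illustrative U5-style motif hierarchy (user-replaceable).
#
# Each entry: clade, parent (null for the root), motif = diagnostic variants
# acquired on the branch leading to the clade, in canonical rCRS-relative
# nomenclature.  This toy rule set mimics the structure of hg U5
# classification (U5 > U5a/U5b > ... > terminal subclusters) but makes no
# claim of matching any published motif table byte-for-byte; replace it with
# your own rules for real analyses.
- clade: U5
  parent: null
  motif: [3197]
- clade: U5a
  parent: U5
  motif: [14793, 16256]
- clade: U5a1
  parent: U5a
  motif: [15218, 16399]
- clade: U5a2
  parent: U5a
  motif: [5495]
- clade: U5a2a
  parent: U5a2
  motif: [16114A, 16192, 16294, 16311]
- clade: U5a2b
  parent: U5a2
  motif: [16362]
- clade: U5b
  parent: U5
  motif: [7768, 16270]
- clade: U5b1
  parent: U5b
  motif: [5656]
- clade: U5b1a
  parent: U5b1
  motif: [16192]
- clade: U5b1b
  parent: U5b1
  motif: [16189]
- clade: U5b2
  parent: U5b
  motif: [16189, 16270]
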