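# Phase-I transformation manifest.  Each rule is applied as a site-directed
# graph edit at the called SOM (see cypsom.metabolites); the SMIRKS-style
# summaries below describe the bond rewiring for audit, they are not executed.
rules:
  - name: s_oxidation
    site: atom (S)
    smirks: "[S:1]>>[S:1]=O"
    example: dimethyl sulfide -> dimethyl sulfoxide
  - name: n_oxidation
    site: atom (N)
    smirks: "[N:1]>>[N+:1][O-]"
    example: trimethylamine -> trimethylamine N-oxide
  - name: p_oxidation
    site: atom (P)
    smirks: "[P:1]>>[P:1]=O"
    example: trimethylphosphine -> trimethylphosphine oxide
  - name: aromatic_hydroxylation
    site: atom (aromatic C with H)
    smirks: "[cH:1]>>[c:1]O"
    example: benzene -> phenol
  - name: dealkylation
    site: atom (sp3 C bonded to N or O)
    smirks: "[C:1][O,N:2]>>[C:1]=O.[O,N:2]"
    note: every single C-N/C-O bond at the carbon is cleaved; if the molecule
      splits, the carbon oxidises to the carbonyl (aldehyde/ketone by H
      count); if it stays whole, no product.
    example: anisole -> phenol + formaldehyde
  - name: ch_hydroxylation
    site: i-H pseudo-bond (C with H, no N/O neighbour)
    smirks: "[CH:1]>>[C:1]O"
    example: toluene -> benzyl alcohol
  - name: epoxidation
    site: bond (C=C)
    smirks: "[C:1]=[C:2]>>[C:1]1[C:2]O1"
    example: ethene -> oxirane
  - name: alcohol_oxidation
    site: bond (C-O, terminal O)
    smirks: "[CH:1][OH:2]>>[C:1]=[O:2]"
    example: ethanol -> acetaldehyde
  - name: heteroatom_o_cleavage
    site: bond (S-O / N-O / P-O; one of several O on S or P)
    smirks: "[S,N,P:1][O:2]>>[S,N,P:1].[O:2]"
    example: dimethyl sulfoxide -> dimethyl sulfide
  - name: nitro_reduction
    site: bond (N-O with several O on N)
    smirks: "[N+:1](=O)[O-]>>[NH2:1]"
    example: nitrobenzene -> aniline
  - name: ring_interconversion
    site: ring (all bonds called)
    smirks: "aromatic ring <-> saturated ring"
    note: aromatic rings saturate to the all-single-bond carbocycle; even
      saturated rings aromatise when a Kekule assignment sanitizes.  The
      hydrogen counts of the product follow standard valence; products are
      flagged with this rule name.
    example: benzene -> cyclohexane
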