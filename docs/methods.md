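# Methods

## Problem and site definition

CYP450-mediated phase-I metabolism is annotated in the source datasets as
*bonds of metabolism* (BOMs): a reacting heavy-atom pair, a hydrogen
replaced on a heavy atom, or a lone-pair reaction on S/P/N.  The package
converts BOMs into a unified *site* space per molecule — every heavy atom,
every heavy-atom bond, and one i–H pseudo-bond per hydrogen-bearing heavy
atom — so that a single classifier can score atoms and bonds together:

1. a heavy-atom BOM i–j marks the bond site (i, j) positive;
2. an i–H BOM marks both the atom site i and the i–H pseudo-bond site
   positive (the reaction involves the atom and its bond to hydrogen);
3. a lone-pair BOM on S/P/N marks the atom site positive.

All other candidate sites are negative.  Hydrogens stay implicit; rule-2
sites are keyed once per heavy atom, not once per hydrogen.  This is one of
the two defensible readings of the negative-count bookkeeping (the other
counts each equivalent hydrogen separately); reported non-SOM counts must be
read against this convention.

The upstream SDF annotation layout is undocumented, so parsing sits behind
one seam: a property per isoform (`BOM_<isoform>`) holding 1-based tokens
`i-j`, `i-H`, `i-LP`, with a user-suppliable field map for other dialects.

## Encoder

Directed message passing with hidden states on directed bonds; the reverse
bond is excluded from aggregation, which prevents a message from bouncing
straight back (two-hop loops).  i–H pseudo-bond sites are realised as bonds
to per-atom pseudo hydrogen vertices carrying a fixed hydrogen encoding, so
they flow through the identical machinery as chemical bonds.

Numerical/architectural choices where the formulation leaves latitude:

- **Combination operator.** The update `h⁰ ⊕ W_m·m` and the readout
  `(hⁿ_vw ⊕ hⁿ_wv)/2` use element-wise addition: the division by two
  requires same-width operands, and addition is the established
  directed-MPNN formulation.  Concatenation would make the bond readout
  ill-typed.
- **Activation.** τ defaults to LeakyReLU with slope 0.01; plain ReLU is
  available as `activation="relu"`.  (The two appear interchangeably in
  descriptions of this architecture family; the leaky variant avoids dead
  units at the small widths used here.)
- **Normalization.** One batch-normalization layer is *shared* by atom and
  bond site outputs, putting both site kinds into one embedding space —
  the precondition for a single discriminator.  Training uses batch
  statistics (momentum 0.1 running updates, eps 1e-5); evaluation uses the
  running averages, making eval forward passes bitwise reproducible.
- **Head.** A single linear layer to two logits with a softmax; the
  positive/negative pair therefore always sums to one.  (Two independent
  sigmoids would be the alternative reading; softmax is what a
  cross-entropy over two exclusive outcomes implies.)
- **Loss.** `loss = a·loss_p + b·loss_n`, cross-entropy *summed* over truly
  positive / truly negative sites.  With a=b=1 this is exactly plain summed
  cross-entropy (asserted to 1e-12 in tests).  The weights counteract the
  strong negative dominance of site data (roughly 10:1 in the reference
  datasets).
- **Molecule features.** Optionally concatenated to every site embedding:
  either the six fixed descriptors (z-scored with training-set statistics)
  or a second, independent D-MPNN whose atom outputs are sum-pooled (mean
  available) and passed through a learned linear map.  The pooling readout
  is not prescribed anywhere; sum keeps size information, and the map lets
  the width be chosen freely.
- **Implementation.** The encoder, its backpropagation, batch-norm, dropout
  (inverted, per-round masks) and the Adam optimizer are written directly
  in NumPy with float64.  All gradients are verified against central
  differences in the test suite's development history and the vectorized
  forward pass is verified against a naive per-bond loop oracle in the
  shipped tests (≤1e-6; observed ~1e-15).
- **Defaults.** hidden width 300, depth 3, dropout 0.05, Adam lr 1e-3,
  30 epochs — conventional values for this architecture family, all
  config-exposed.  The demonstration experiments use a reduced scale
  (width 48, depth 2, 4 epochs, 80–200 molecules), which is ample for the
  planted synthetic rules; `experiments.DEMO_CONFIG` records it.

## Discriminator and training protocol

After each encoder epoch an XGBoost classifier (binary-logistic objective;
Jaccard, precision, recall and F1 reported on train and validation splits;
`n_estimators`, `reg_lambda`, `max_depth`, `colsample_bytree` exposed
per isoform) is retrained from scratch on the target isoform's site
embeddings.  The retained model is the epoch with the highest validation
Jaccard, earlier epoch on ties.  A `booster_every=k` flag thins the
per-epoch retraining for speed; the final epoch is always scored.

The encoder pools (molecule, isoform) instances: the target isoform
contributes its 80 % training split, every other isoform all of its
molecules; each instance is an independent binary training example sharing
the encoder.  Splits are at molecule granularity (sites of one molecule
never straddle the split); train size is round(0.8·N) half-away-from-zero.
One master seed fans out (via `SeedSequence.spawn`) to split, initialisation,
dropout, shuffling and the booster, making two runs with the same seed
identical to the byte.

**Operating modes.** Precision mode leaves `scale_pos_weight` at 1.  Recall
mode sets it to `c·N_neg/N_pos`, raising the positive-class weight on
imbalanced data — the direction a recall mode requires.  The inverted ratio
`c·N_pos/N_neg` (which *lowers* the weight and appears in some descriptions
of this scheme, presumably a typographical slip) is exposed as
`weight_formula="pos_over_neg"` rather than silently resolved.

Calls use a fixed probability threshold of 0.5.

## Metabolite rules

Each called site maps to at most one phase-I archetype, applied as a
site-directed RDKit graph edit (S/N/P-oxidation, aromatic and aliphatic
hydroxylation, dealkylation with carbonyl formation on fragmentation,
epoxidation, carbinol oxidation, heteroatom–O cleavage, nitro reduction,
aromatic/non-aromatic ring interconversion).  Site-directed application —
transform *this* atom, not every SMARTS match — is awkward to express with
reaction-SMIRKS engines, so the edits are code; a YAML manifest
(`data/reaction_rules.yaml`) documents each rule with a SMIRKS-style summary
for audit.  Choices in under-specified corners:

- "further oxidise the cleaved carbon" is implemented as conversion to the
  corresponding carbonyl (aldehyde or ketone by remaining hydrogen count),
  the chemistry O-/N-dealkylation encodes;
- dealkylation cleaves only *single* C–N/C–O bonds (carbonyls stay);
- C–O bond oxidation applies to terminal (carbinol) oxygens; an in-chain
  ether C–O delegates to dealkylation at the carbon;
- N-oxides are emitted charge-separated ([N+][O-]) to keep nitrogen at
  standard valence;
- ring interconversion saturates an aromatic ring to the all-single-bond
  ring, and aromatises an even saturated ring when a Kekulé assignment
  sanitizes; hydrogen counts follow standard valence and such products are
  flagged with the rule name;
- a lone detached oxygen (water) is dropped from product sets; products are
  canonicalised and deduplicated; generation is single-step (no recursive
  metabolism).

## Metrics

Jaccard J = TP/(TP+FP+FN), precision, recall, F1; for pooled counts
F1 = 2J/(1+J) (a test asserts the identity).  Ratios with zero denominator
are defined as 0 with a logged note — this touches only degenerate
evaluation slices.  Cross-isoform aggregates are SOM-count-weighted (micro)
averages; report tables round half-up to three decimals.  Metabolite-level
metrics are set-overlap metrics over canonical product SMILES.

## Synthetic data: what it shows and what it does not

`fixtures.make_molecules` assembles molecules from a fragment grammar
(sampled ring systems and chains plus substituents joined by single bonds),
guaranteeing valence-correct, sanitizable structures of 5–25 heavy atoms
over C/H/O/N/S/P — random graphs would test the sanitizer, not the
pipeline.  `fixtures.plant_soms` marks sites positive by a descriptor-level
predicate (e.g. "every sulfur atom", "aromatic C–H next to oxygen"),
optionally flipped with probability ε, and emits annotations in the same
dialect the SDF reader consumes (labels round-trip exactly; the empirical
flip rate is checked binomially).

Passing the learnability experiments shows the plumbing is sound: features
reach the discriminator intact, training optimises the intended loss, seeds
reproduce, and the label-permutation control collapses to baseline — i.e.
nothing leaks.  It does *not* show the model captures real CYP450
regioselectivity: planted rules are far simpler than enzyme-substrate
recognition, and synthetic molecules are smaller and cleaner than drug-like
chemistry.  Claims about real regioselectivity require the upstream
annotated datasets, which are not redistributable inside this repository;
given those files, `read_annotated_sdf` + `label_soms` + `som_count_table`
reproduce the published record and label counts, and the full training
protocol applies unchanged.

## Known limitations

- The i–H counting convention (once per heavy atom) is one of two readings
  of the published non-SOM counts.
- Ring interconversion's exact tautomer/Kekulé outcome is normalised, not
  predicted.
- Per-isoform tuned hyperparameters of the reference tool are not published
  in the body of its description; they are config inputs here, not defaults.
- Probabilities are raw booster outputs; no calibration is applied.
- No 3-D information: only graph topology is consumed.
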