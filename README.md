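# cypsom

Site-of-metabolism (SOM) prediction for the nine major human cytochrome P450
isoforms (CYP1A2, 2A6, 2B6, 2C8, 2C9, 2C19, 2D6, 2E1, 3A4), with
rule-based derivation of the resulting phase-I metabolites.  It is aimed at
drug-metabolism and metabolomics scientists who want, from a table of SMILES
strings, a ranked list of the atoms and bonds a CYP isoform is likely to
attack and the structures those attacks would produce.

## The model

Candidate sites of a substrate are its heavy atoms, its heavy-atom bonds and
one i–H pseudo-bond per hydrogen-bearing heavy atom; atom and bond sites
share one key space so a single discriminator scores both.  A directed
message-passing neural network (D-MPNN) embeds every site: hidden states
h_vw live on *directed* bonds,

    h⁰_vw = τ(W_a [x_v, e_vw])
    m^{t+1}_vw = Σ_{k∈N(v), k≠w} h^t_kv        (reverse bond excluded)
    h^{t+1}_vw = drop(τ(h⁰_vw + W_m m^{t+1}_vw))

and after n rounds the readout gives, under one shared batch-normalization
layer B,

    F_vw = B((hⁿ_vw + hⁿ_wv)/2)
    F_v  = B(drop(τ(W_o [x_v, Σ_w hⁿ_vw]))).

The reverse-bond exclusion k≠w is what prevents two-hop message loops.  The
encoder is trained with a class-weighted cross-entropy, loss = a·loss_p +
b·loss_n (positive and negative sites weighted separately — site data are
heavily negative-dominated), through a single-layer softmax head.  The
*real* discriminator is an XGBoost booster (binary-logistic objective,
Jaccard score J = TP/(TP+FP+FN) as the evaluation and selection metric)
retrained on the embeddings after every encoder epoch; the epoch with the
best validation Jaccard is retained.  The encoder pools training data across
all nine isoforms while each booster sees only its target isoform.  Two
operating modes differ only in the booster's positive-class weight:
**precision mode** (default weight, fewer but surer calls) and **recall
mode** (`scale_pos_weight = c·N_neg/N_pos`, more complete calls).  Sites with
probability > 0.5 are called SOMs and mapped to metabolites by deterministic
phase-I rules (hydroxylation, epoxidation, S/N/P-oxidation, dealkylation,
nitro reduction, ring interconversion; see
`src/cypsom/data/reaction_rules.yaml`).

An optional whole-molecule feature block — either six fixed descriptors
(MolWt, H-bond acceptors/donors, logP, TPSA, Labute ASA) or a second,
independent D-MPNN — can be concatenated to every site embedding.

## Worked example

Train on a synthetic dataset whose planted rule is "every sulfur atom is a
SOM", then predict two query molecules:

```bash
cypsom fixtures --out-sdf demo.sdf --n 60 --rule sulfur_atoms --isoform 3A4 --seed 11
printf 'hidden_size: 48\ndepth: 2\nepochs: 4\n' > cfg.yaml
cypsom train demo.sdf --out bundle --isoform 3A4 --config cfg.yaml --seed 11
printf 'id,smiles\nthioanisole,CSc1ccccc1\nanisole,COc1ccccc1\n' > query.csv
cypsom predict bundle query.csv --out-dir report
```

Training prints `best epoch 3, validation Jaccard 1.000` — the booster of
epoch 3 separated the held-out planted sites perfectly.  `report/sites.tsv`
ranks every candidate site per molecule:

```
mol_id       site_kind  atoms  probability  called
thioanisole  atom       1      0.9256716    True
thioanisole  atom       5      0.00539921   False
...
```

The sulfur (atom 1) is called at probability 0.93; every other site is far
below the 0.5 threshold, and anisole (no sulfur) gets no calls.
`report/metabolites.tsv` maps the called site through the S-oxidation rule:

```
parent_id    rule         site    product_smiles
thioanisole  s_oxidation  atom:1  CS(=O)c1ccccc1
```

i.e. methyl phenyl sulfoxide.  `cypsom eval bundle demo.sdf --out eval.tsv`
scores the model against the reference labels (Jaccard/precision/recall/F1
per isoform plus a SOM-count-weighted average column).

## Layout

- `src/cypsom/chem.py` — annotated SDF I/O, SOM labeling rules, splits, counts
- `src/cypsom/featurize.py` — atom/bond/molecule descriptors
- `src/cypsom/encoder.py` — directed message passing, head, weighted loss (NumPy)
- `src/cypsom/model.py` — `SitePredictor` estimator (sklearn API), XGBoost discriminator, modes
- `src/cypsom/metabolites.py` — phase-I reaction rules
- `src/cypsom/metrics.py` — confusion metrics, weighted averages, report tables
- `src/cypsom/fixtures.py` — synthetic molecules with planted SOM rules
- `src/cypsom/benchmarks.py` — published reference numbers used for verification
- `src/cypsom/experiments.py` — learnability / mode-comparison protocols
- `src/cypsom/cli.py` — `cypsom` command (`fixtures`, `features`, `train`, `predict`, `metabolites`, `eval`)
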