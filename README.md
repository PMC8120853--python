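# lpicaps

Prediction of lncRNA–protein interactions (LPI) from sequence alone, using
four groups of multimodal features and a multichannel capsule network.

Most long noncoding RNAs act by binding proteins, but experimentally mapping
those interactions is slow and expensive, and known interaction catalogues
cover only a tiny corner of the lncRNA × protein candidate space. `lpicaps`
is for computational biologists who have lncRNA and protein sequences (plus
a catalogue of known interacting pairs) and want a ranked list of candidate
partners.

## Model

Each lncRNA–protein pair is encoded as four fixed-dimension feature vectors:

| channel | content | dims |
|---|---|---|
| SF | lncRNA 4-mer frequencies (256) ‖ protein 3-mer frequencies over a 4-group reduced amino-acid alphabet (64) | 320 |
| Mtf | counts of 18 lncRNA motifs and 11 protein motifs (editable config) | 29 |
| PC | 10-term cosine spectra of 2 RNA + 8 protein physicochemical profiles | 100 |
| SS | 10-term spectra of the RNA paired/unpaired profile and the protein state-propensity profile | 20 |

k-mer frequencies follow f_i = n_i / Σ_j n_j over all overlapping windows.
Variable-length numeric profiles are compressed by the DCT-IV-type series
X′_k = √(2/L) Σ_{n=0}^{L−1} X_n cos[(π/L)(n+½)(k+½)], k = 0…9. RNA secondary
structure comes from a built-in maximum-base-pair Nussinov fold (or RNAfold
via an adapter); protein secondary structure from a Chou–Fasman propensity
scan (or Predator via an adapter).

Each channel feeds a 5-layer fully connected subnetwork (PReLU, dropout)
ending in a 3-dim capsule U_i. Learned 3×3 matrices W_i project the capsules
into a shared prediction space; the sum S = Σ W_i U_i is squashed,

  V = (‖S‖² / (1 + ‖S‖²)) · (S / ‖S‖),

and ‖V‖ ∈ [0, 1) is the interaction score (call = score > threshold). The
capsule stage trains exactly 4 · 3² = 36 parameters. Class imbalance in the
candidate universe is handled by EasyEnsemble: the negatives are partitioned
into positive-sized subsets, one model is trained per subset, and the
ensemble score is the mean member score.

## Worked example

The built-in simulator plants a motif-based interaction rule (a pair
interacts iff its RNA contains the Fox1 element UGCAUG and its protein an
RGG box) into otherwise random sequences:

```sh
lpi simulate --out data --seed 4 --n-rna 30 --n-protein 20 --motif-fraction 0.6
# wrote 30 RNAs, 20 proteins, 600 pairs (240 positive) to data

lpi train --rna-fasta data/rna.fasta --protein-fasta data/protein.fasta \
    --pairs data/pairs.tsv --out model.npz --members 3 --epochs 40 --seed 1
# trained 1 member(s) on 240 positives x 1 balanced subsets ... -> model.npz

lpi predict --model model.npz --rna-fasta data/rna.fasta \
    --protein-fasta data/protein.fasta --pairs data/pairs.tsv --out scores.tsv
# scored 600 pairs (threshold 0.5) -> scores.tsv

head -4 scores.tsv
# rna_id  protein_id  score     call
# rna0000 prot0000    0.176928  no_interact
# rna0000 prot0001    0.047941  no_interact
# rna0000 prot0002    0.831763  interact

lpi evaluate --scores scores.tsv --pairs data/pairs.tsv
# {
#   "accuracy": 0.9333333333333333,
#   "precision": 0.8623188405797102,
#   "recall": 0.9916666666666667,
#   "f_value": 0.9224806201550387,
#   "auc": 0.9879166666666666,
#   "auprc": 0.9812652702572071,
#   ...
# }
```

Scores near 1 mean the summed capsule is long — the channels agree, in both
prediction propensity and orientation, that the pair interacts. Here the
model recovers the planted rule on the training pairs with F-value 0.92 and
AUC 0.99; a stricter held-out version of this experiment (fresh sequences in
every test pair, plus a motif-channel ablation) lives in the test suite.

The same commands run on real data: FASTA files plus a TSV manifest
(`rna_id<TAB>protein_id[<TAB>label]`). Everything the CLI does is also
available as a library (`lpicaps.features.FeaturePipeline`,
`lpicaps.capsnet.train_ensemble`, `lpicaps.metrics.cross_validate`, ...).

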