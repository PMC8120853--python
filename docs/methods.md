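# Methods

## Problem and data model

The package predicts whether a given lncRNA and protein interact, from
sequence alone. Interacting pairs come from a curated catalogue; negatives
are not observed, so the negative universe is the full lncRNA × protein
cross product minus the known positives. For the catalogue scale the
package is designed around (thousands of lncRNAs, tens of proteins),
negatives outnumber positives by roughly 30:1, so training uses
EasyEnsemble: the shuffled negatives are partitioned into disjoint subsets
of exactly the positive-set size (floor division; the leftover pairs are
discarded and their count logged), one model is trained per balanced
subset, and prediction averages the member scores. Floor partitioning with
a logged discard was chosen over ragged subsets so that every member sees
an exactly balanced problem.

## Feature channels

**Sequence composition (SF, 320 dims).** Overlapping 4-mer frequencies
over {A,C,G,U} for the lncRNA (256) and overlapping 3-mer frequencies for
the protein after reduction to four physicochemical groups — {D,E},
{H,R,K}, {C,G,N,Q,S,T,Y,A}, {F,I,L,M,P,V,W} — (64). Frequencies are
normalized by the number of valid windows; windows containing an unknown
residue (N/X) are excluded from numerator and denominator, so unknowns
never fabricate signal. Sequences shorter than k yield a zero vector with
a warning rather than an error. Indexing is lexicographic (A<C<G<U; group
order 1<2<3<4), fixed for reproducibility.

**Motif counts (Mtf, 29 dims).** Raw overlapping-occurrence counts of 18
lncRNA motifs and 11 protein motifs, in a fixed order, with the pattern
strings held in an editable YAML config. RNA patterns may use IUPAC
degeneracy codes; protein patterns are literal. A group motif (the final
RNA entry) counts the sum of its members. The shipped patterns are
consensus elements from the published motif literature (Fox1 UGCAUG, Nova
YCAY, PTB CUCUCU, ARE AUUUA, PUM UGUANAUA, ...); for factors whose
consensus varies between studies one widely cited form was chosen. The
18+11 layout is the contract; the pattern strings are configuration.
Overlapping counting is deliberate: the dipeptide-style motifs (KK, HR/RH)
only make sense with overlaps. Counts are raw integers — "number of
occurrences" — not length-normalized.

**Physicochemical spectra (PC, 100 dims).** Each sequence is mapped to
per-residue numeric profiles (RNA: hydrogen-bond capacity and a van der
Waals contact scale; protein: Bull & Breese, Kyte & Doolittle, Zimmerman
polarity, Grantham polarity, isoelectric point, bulkiness, Eisenberg
hydrophobicity, Hopp & Woods hydrophilicity — AAindex scales), and each
profile is compressed to its first 10 cosine-series terms

    X'_k = sqrt(2/L) · Σ_{n=0}^{L−1} X_n cos[(π/L)(n+½)(k+½)],  k = 0..9,

a DCT-IV-type transform, giving a length-independent encoding. The upper
summation bound is L−1: the profile has entries X_0..X_{L−1}, and the
transform at L ≥ 10 coincides with the orthonormal DCT-IV restricted to
10 terms (cross-checked against scipy in the tests). For L < 10 the sum
simply runs over the available positions and the spectrum stays length 10.
The two RNA tables are surrogate scales (Watson-Crick bond count;
heavy-atom count) standing in the same roles as the hydrogen-bonding and
van der Waals propensities used by earlier LPI tools; all tables are
editable TSV configuration, and exchanging them changes the feature
fingerprint (see below).

**Secondary-structure spectra (SS, 20 dims).** The RNA structure is
predicted by a built-in Nussinov maximum-base-pair dynamic program
(Watson-Crick + GU wobble, minimum hairpin loop 3, deterministic
tie-breaking: leave the 5'-most base unpaired when that loses nothing,
else pair it with the smallest admissible partner) and binarized to a
paired/unpaired profile. Protein structure comes from a classical
Chou–Fasman scan (helix nucleation: ≥4 formers in a window of 6; sheet:
≥3 in 5; bidirectional extension while a 4-residue edge window averages
propensity > 1; block-wise overlap resolution by higher mean propensity;
remainder coil), and each residue is encoded by its propensity for its
predicted state (P_helix if H, P_sheet if E, P_turn if C — the natural
reading of "encode the state string by the propensities", though other
mappings are conceivable). Both profiles are compressed by the same
10-term transform. Built-in predictors are the default so the pipeline
runs with zero external installs; adapters shell out to RNAfold
(thermodynamic MFE folding) or Predator where available and parse their
plain-text output. The Nussinov fold maximizes pair count, not free
energy; it is a desk-scale stand-in whose output has the same type and
invariants as RNAfold's.

## Classifier

Each enabled channel feeds its own 5-layer fully connected subnetwork
(PReLU with a learnable scalar slope per hidden layer, dropout on hidden
activations) ending in a 3-dimensional capsule. A learned 3×3 matrix per
channel projects the capsules into a shared prediction space; the
projected capsules are summed and squashed, and the squashed length is
the score. No dynamic routing: with a single output capsule there is
nothing to route. The capsule stage therefore trains exactly
n_channels · 3² parameters (36 for four channels). Closing a channel
removes its subnet and matrix entirely.

Training minimizes the single-capsule margin loss
L = y·max(0, 0.9 − ‖V‖)² + 0.5·(1−y)·max(0, ‖V‖ − 0.1)² with mini-batch
Adam. The loss follows the capsule-network literature; the paper-scale
hyperparameters are not published, so the defaults here (lr 1e-3, batch
64, 80 epochs, dropout 0.2, decoupled weight decay 1e-4 on weight
matrices) were fixed during development on the synthetic planted-signal
task and are all configurable. A decision at exactly the threshold is
negative (the rule is strictly greater-than); the default threshold is
0.5, configurable (e.g. 0.87 for high-confidence screening).

Two numerical choices matter in practice:

- **Input standardization.** Each member standardizes every feature
  dimension (mean/sd fit on its balanced training set, stored in the
  model file). Raw motif counts grow linearly with sequence length; at
  realistic lengths they drive ‖S‖ into the flat region of the squash at
  initialization, the score saturates near 1 for every input and
  gradients vanish. Standardization removes this failure mode.
- **Subnet capacity.** Default hidden widths follow a geometric taper
  from min(input_dim, 32) down to 3. With an uncapped taper the 320-dim
  channel's first hidden layer alone carries ~40k weights and a
  desk-scale training set is memorized outright — held-out performance
  collapses and channel-ablation experiments become meaningless. The cap
  is configurable per channel; the 5-layer / 3-dim-output contract is
  fixed.

Scoring is deterministic; training is reproducible bit-for-bit under a
seed (one generator drives shuffling and dropout; member seeds derive
from a SeedSequence). Models serialize to a single .npz container holding
all weights, the scaler, hyperparameters and a fingerprint of the feature
configuration (channel layout + motif and property tables); prediction
with a mismatched feature configuration is refused rather than silently
mis-scored.

## Evaluation

Accuracy, precision, recall and F-value come from confusion counts under
the same strict-greater-than rule as the classifier; zero-denominator
ratios are reported as 0 with an `undefined` flag instead of raising, so
sweeps over degenerate folds never crash. AUC is the trapezoidal ROC area
and AUPRC the step-interpolated precision-recall area (scikit-learn);
both are cross-checked against an O(n²) concordance oracle in the tests.
Cross-validation uses stratified folds (class balance per fold; the
choice is ours — unstratified folds at 30:1 imbalance routinely produce
degenerate test sets).

## Synthetic data

The generator emits uniform-random backbone sequences (RNA 120–240 nt,
protein 80–160 aa by default), plants an RNA motif (Fox1's UGCAUG) and a
protein motif (the RGG box) into a configurable fraction of sequences
(default 0.5), and labels a pair positive iff its RNA contains the RNA
motif and its protein the protein motif — evaluated on the final
sequences, so chance occurrences count as real rule hits and noise-free
labels are exactly Bayes-consistent with the motif channel. Optional
label flips model annotation noise. Two pairing modes exist: `cross`
(every RNA × every protein — the candidate-universe shape of real
catalogues) and `matched` (the i-th RNA with the i-th protein, fresh
sequences in every pair).

The planted-signal recovery experiment in the test suite uses `matched`
pairing with 2000 pairs and motif fraction 0.45 (so the ~20% positive
rate leaves enough negatives for the three balanced ensemble subsets).
Matched pairing is essential for that experiment: when sequences recur
across pairs, a held-out pair still consists of seen sequences, every
channel can memorize sequence identity, and neither held-out recovery nor
channel ablation measures anything about the planted rule. Under matched
pairing the full model recovers the rule on held-out pairs (AUC ≥ 0.95,
F ≥ 0.9) and closing the motif channel costs ≥ 0.1 AUC, because the
composition channels see the planted 6-mer only as a ~1σ perturbation of
the 4-mer profile while the motif channel sees an exact count.

What passing these tests shows — and does not show: the pipeline
end-to-end can extract a clean combinatorial sequence signal from
realistic-length sequences under class imbalance. Real lncRNA binding is
not a single-motif AND rule; the synthetic data has uniform base
composition, no GC structure, no homology between sequences and no
binding thermodynamics, so synthetic performance says nothing about
accuracy on real catalogues.

## Degenerate inputs and conventions

- RNA input may use T; it is transliterated to U on ingest. Ambiguity
  codes fold to N (RNA) / X (protein) with a warning; other characters
  are errors. Duplicate FASTA ids and duplicate manifest pairs are
  errors (manifests are id-keyed).
- Unknown residues never match motifs (not even the degenerate code N)
  and contribute 0.0 to numeric profiles.
- The all-zero capsule squashes to the all-zero vector (score 0), the
  limit convention.
- An empty numeric profile is an error; a profile shorter than 10 is not.

## Known limitations

- The Nussinov fold is cubic in sequence length (numba-jitted); very long
  transcripts (≫ 2 kb) are slow, and maximum-pairing structures differ
  from MFE structures — use the RNAfold adapter when fidelity matters.
- The shipped motif patterns and RNA property scales are literature
  defaults, not a published reference set; conclusions that hinge on a
  specific motif's count should pin their own config.
- Scores are ensemble means of margin-trained members, not calibrated
  probabilities; thresholds should be chosen on validation data.
- Training is pure NumPy on CPU; it is comfortable at 10⁴–10⁵ pairs and
  not intended for GPU-scale corpora.
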