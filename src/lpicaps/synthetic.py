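"""Synthetic lncRNA-protein datasets with a planted, recoverable signal.

Backbone sequences are i.i.d. uniform over their alphabet; a planted RNA
motif and a planted protein motif are written into a configured fraction
of sequences, and a pair interacts iff its RNA contains the RNA motif AND
its protein contains the protein motif (evaluated on the final sequences,
so chance occurrences count too).  Labels are then flipped independently
with probability ``noise_rate``.  The planted motifs default to members of
the shipped motif table (Fox1's UGCAUG; the RGG box), so the signal is
directly visible to the motif channel -- which makes per-channel ablation
experiments meaningful at synthetic scale.

These fixtures emulate only what the pipeline contracts need: realistic
lengths and alphabets with a clean combinatorial interaction rule.  They
do not emulate real lncRNA composition, GC content or binding energetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lpicaps.io_dataset import (
    PROTEIN_ALPHABET,
    RNA_ALPHABET,
    PairRecord,
    SequenceRecord,
)

#: planted motifs; both are entries of the default motif table
RNA_SIGNAL_MOTIF = "UGCAUG"  # Fox1 recognition element
PROTEIN_SIGNAL_MOTIF = "RGG"  # RGG box


@dataclass
class SyntheticConfig:
    n_rna: int = 50
    n_protein: int = 40
    rna_len_range: tuple[int, int] = (120, 240)
    prot_len_range: tuple[int, int] = (80, 160)
    rna_motif: str = RNA_SIGNAL_MOTIF
    prot_motif: str = PROTEIN_SIGNAL_MOTIF
    motif_fraction: float = 0.5
    noise_rate: float = 0.0
    #: "cross" pairs every RNA with every protein (the candidate-universe
    #: shape of real LPI catalogues); "matched" pairs the i-th RNA with the
    #: i-th protein so every pair carries fresh, never-repeated sequences --
    #: the right shape for held-out signal-recovery experiments, where
    #: repeated sequences would let a model memorize identity instead of
    #: learning the planted rule
    pairing: str = "cross"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pairing not in ("cross", "matched"):
            raise ValueError("pairing must be 'cross' or 'matched'")
        if self.pairing == "matched" and self.n_rna != self.n_protein:
            raise ValueError("matched pairing requires n_rna == n_protein")
        if not 0.0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must be in [0, 0.5)")
        if self.rna_len_range[0] < max(4, len(self.rna_motif)):
            raise ValueError("RNA length range too short for k-mers/motif")
        if self.prot_len_range[0] < max(3, len(self.prot_motif)):
            raise ValueError("protein length range too short for k-mers/motif")


def _random_seq(rng: np.random.Generator, alphabet: str, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(alphabet), size=length))


def _plant(rng: np.random.Generator, seq: str, motif: str) -> str:
    pos = int(rng.integers(0, len(seq) - len(motif) + 1))
    return seq[:pos] + motif + seq[pos + len(motif) :]


def generate(
    config: SyntheticConfig,
) -> tuple[list[SequenceRecord], list[SequenceRecord], list[PairRecord]]:
    """Generate sequences and the fully labeled pair cross product."""
    rng = np.random.default_rng(config.seed)
    rnas = []
    for i in range(config.n_rna):
        seq = _random_seq(rng, RNA_ALPHABET, *config.rna_len_range)
        if rng.random() < config.motif_fraction:
            seq = _plant(rng, seq, config.rna_motif)
        rnas.append(SequenceRecord(id=f"rna{i:04d}", seq=seq, kind="rna"))
    proteins = []
    for i in range(config.n_protein):
        seq = _random_seq(rng, PROTEIN_ALPHABET, *config.prot_len_range)
        if rng.random() < config.motif_fraction:
            seq = _plant(rng, seq, config.prot_motif)
        proteins.append(SequenceRecord(id=f"prot{i:04d}", seq=seq, kind="protein"))
    if config.pairing == "cross":
        combos = [(r, p) for r in rnas for p in proteins]
    else:
        combos = list(zip(rnas, proteins))
    pairs = []
    for r, p in combos:
        interact = (config.rna_motif in r.seq) and (config.prot_motif in p.seq)
        if config.noise_rate > 0 and rng.random() < config.noise_rate:
            interact = not interact
        pairs.append(
            PairRecord(
                rna_id=r.id,
                protein_id=p.id,
                label="positive" if interact else "negative",
            )
        )
    return rnas, proteins, pairs


#: fixed short pair with hand-verified feature fragments (see tests)
GOLDEN_RNA = SequenceRecord(id="golden_rna", seq="ACGUACGUACGU", kind="rna")
GOLDEN_PROTEIN = SequenceRecord(id="golden_prot", seq="MKDEHRKFILAA", kind="protein")


def golden_pair():
    """A fixed (RNA, protein) pair plus expected feature fragments.

    The expected values were computed with the brute-force oracles in the
    test suite and frozen here: 4-mer frequencies are counts over the 9
    overlapping windows of the RNA; the reduced protein string follows the
    4-group alphabet; motif counts are overlapping-occurrence counts.
    """
    expected = {
        # RNA 4-mer frequencies (all other 4-mers are 0)
        "rna_kmers": {"ACGU": 3 / 9, "CGUA": 2 / 9, "GUAC": 2 / 9, "UACG": 2 / 9},
        # protein mapped onto groups 1={D,E} 2={H,R,K} 3={C,G,N,Q,S,T,Y,A} 4={F,I,L,M,P,V,W}
        "reduced_protein": "421122244433",
        # each of the 10 overlapping reduced 3-mers occurs exactly once
        "protein_kmer_value": 1 / 10,
        # protein motif counts in table order
        "protein_motif_counts": {
            "H_or_R": 2, "HR_RH": 1, "E": 1, "K": 2, "H": 1, "R": 1,
            "EE": 0, "KK": 0, "RS_SR": 0, "RGG": 0, "YGG": 0,
        },
        # all named RNA motifs and the AU/UG dimers are absent
        "rna_motif_total": 0,
        # first 4 cosine-series terms of the RNA hydrogen-bond profile
        # [2,3,3,2]*3, from the double-loop summation oracle
        "rna_hbond_spectrum_head": [
            7.816002975674, -2.658868345946, 1.670282511846, -1.302098812508,
        ],
    }
    return GOLDEN_RNA, GOLDEN_PROTEIN, expected
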