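"""Sequence-composition features.

lncRNAs are encoded by 4-mer frequencies over {A,C,G,U} (256 dims).
Proteins are first reduced to a 4-group physicochemical alphabet and then
encoded by 3-mer frequencies over the groups (64 dims).  The concatenated
pair vector is 320-dimensional, lncRNA block first.

The frequency of the i-th k-mer is f_i = n_i / sum_j n_j, counting all
overlapping length-k windows (stride 1).  Windows containing an unknown
residue are excluded from both numerator and denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np

from lpicaps.io_dataset import RNA_ALPHABET, SequenceRecord

#: 4-group reduced amino-acid alphabet: acidic {D,E}; basic {H,R,K};
#: small/polar {C,G,N,Q,S,T,Y,A}; hydrophobic {F,I,L,M,P,V,W}.
REDUCED_GROUPS: tuple[str, ...] = ("DE", "HRK", "CGNQSTYA", "FILMPVW")
REDUCED_ALPHABET = "1234"
_REDUCE_MAP = {
    aa: REDUCED_ALPHABET[g] for g, members in enumerate(REDUCED_GROUPS) for aa in members
}
#: marker for residues outside the 20-letter alphabet; never counted
INVALID = "?"

RNA_K = 4
PROTEIN_K = 3
RNA_KMER_DIM = 4**RNA_K  # 256
PROTEIN_KMER_DIM = 4**PROTEIN_K  # 64
PAIR_SEQUENCE_DIM = RNA_KMER_DIM + PROTEIN_KMER_DIM  # 320


@dataclass
class KmerVector:
    """Frequencies of all alphabet_size**k k-mers in lexicographic order."""

    values: np.ndarray
    k: int
    alphabet_size: int

    def __post_init__(self) -> None:
        assert len(self.values) == self.alphabet_size**self.k


def kmer_frequencies(seq: str, k: int, alphabet: str) -> KmerVector:
    """Overlapping k-mer frequencies of ``seq`` over an ordered alphabet.

    The vector is indexed lexicographically (the k-mer is read as a base-
    ``len(alphabet)`` numeral).  Sequences with no valid window yield the
    all-zero vector with a warning rather than an error.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    size = len(alphabet)
    index = {ch: i for i, ch in enumerate(alphabet)}
    counts = np.zeros(size**k)
    for start in range(len(seq) - k + 1):
        window = seq[start : start + k]
        idx = 0
        for ch in window:
            pos = index.get(ch)
            if pos is None:
                break
            idx = idx * size + pos
        else:
            counts[idx] += 1
    total = counts.sum()
    if total > 0:
        counts /= total
    else:
        warnings.warn(
            f"no valid {k}-mer window in sequence of length {len(seq)}; "
            "returning all-zero k-mer vector",
            stacklevel=2,
        )
    return KmerVector(values=counts, k=k, alphabet_size=size)


def reduce_protein(seq: str) -> str:
    """Map a protein sequence onto the 4-group reduced alphabet.

    Same length as the input; residues outside the 20-letter alphabet
    become the invalid marker and are excluded from k-mer windows.
    """
    return "".join(_REDUCE_MAP.get(aa, INVALID) for aa in seq)


def kmer_names(k: int, alphabet: str) -> list[str]:
    """Lexicographic k-mer labels matching the vector index order."""
    return ["".join(t) for t in product(alphabet, repeat=k)]


def pair_sequence_features(rna: SequenceRecord, protein: SequenceRecord) -> np.ndarray:
    """320-dim sequence-composition vector: [RNA 4-mers | protein 3-mers]."""
    if rna.kind != "rna" or protein.kind != "protein":
        raise ValueError("expected (rna, protein) records in that order")
    rna_vec = kmer_frequencies(rna.seq, RNA_K, RNA_ALPHABET).values
    prot_vec = kmer_frequencies(
        reduce_protein(protein.seq), PROTEIN_K, REDUCED_ALPHABET
    ).values
    return np.concatenate([rna_vec, prot_vec])
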