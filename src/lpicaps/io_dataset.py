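"""Sequence and pair-manifest I/O, negative-universe construction and
balanced partitioning for EasyEnsemble.

Interacting pairs come from a curated catalogue; non-interacting pairs are
not observed, so the negative universe is the full lncRNA x protein cross
product minus the known positives.  Because negatives then outnumber
positives by orders of magnitude, they are partitioned into disjoint
positive-sized subsets, one balanced training set per ensemble member.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = "ACGU"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: the explicit "unknown residue" symbol per molecule kind
UNKNOWN = {"rna": "N", "protein": "X"}
#: IUPAC ambiguity codes (RNA) and non-standard amino acids folded into the
#: unknown symbol on ingest; anything else is a hard error
_RNA_AMBIGUOUS = set("RYSWKMBDHVN")
_PROTEIN_AMBIGUOUS = set("XBZUO*")


class ValidationError(ValueError):
    """Raised when an input record violates a dataset invariant."""


@dataclass(frozen=True)
class SequenceRecord:
    """An identified lncRNA or protein sequence with a validated alphabet."""

    id: str
    seq: str
    kind: str  # "rna" | "protein"

    def __post_init__(self) -> None:
        if self.kind not in ("rna", "protein"):
            raise ValidationError(f"unknown sequence kind {self.kind!r}")
        if not self.seq:
            raise ValidationError(f"empty sequence for id {self.id!r}")


@dataclass(frozen=True)
class PairRecord:
    """One lncRNA-protein pair with an optional binary interaction label."""

    rna_id: str
    protein_id: str
    label: str = "unlabeled"  # "positive" | "negative" | "unlabeled"

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative", "unlabeled"):
            raise ValidationError(f"bad label {self.label!r}")


@dataclass
class BalancedSplit:
    """Positives plus disjoint equal-size negative subsets."""

    positives: list[PairRecord]
    negative_subsets: list[list[PairRecord]]
    subset_size: int
    n_discarded: int = 0

    def __post_init__(self) -> None:
        for sub in self.negative_subsets:
            if len(sub) != self.subset_size:
                raise ValidationError(
                    f"negative subset of size {len(sub)} != {self.subset_size}"
                )


def clean_sequence(raw: str, kind: str, *, id: str = "?") -> str:
    """Upper-case, transliterate T->U for RNA, fold ambiguity codes into the
    unknown symbol, and reject characters outside the declared alphabet."""
    seq = raw.upper().replace(" ", "").replace("-", "")
    if kind == "rna":
        seq = seq.replace("T", "U")
        alphabet, ambiguous = set(RNA_ALPHABET), _RNA_AMBIGUOUS
    else:
        alphabet, ambiguous = set(PROTEIN_ALPHABET), _PROTEIN_AMBIGUOUS
    unknown = UNKNOWN[kind]
    out = []
    n_unknown = 0
    for ch in seq:
        if ch in alphabet:
            out.append(ch)
        elif ch in ambiguous or ch == unknown:
            out.append(unknown)
            n_unknown += 1
        else:
            raise ValidationError(
                f"illegal character {ch!r} in {kind} sequence {id!r}"
            )
    if n_unknown:
        warnings.warn(
            f"{n_unknown} unknown residue(s) in {kind} {id!r} mapped to "
            f"{unknown!r}; they are excluded from k-mer windows and motif "
            "matches and contribute 0.0 to numeric profiles",
            stacklevel=2,
        )
    if not out:
        raise ValidationError(f"sequence {id!r} empty after cleaning")
    return "".join(out)


def read_fasta(path: str | Path, kind: str) -> list[SequenceRecord]:
    """Read a FASTA file into validated records, in file order.

    RNA entries may use the DNA alphabet (T is transliterated to U).
    Duplicate ids are rejected: downstream pair manifests are id-keyed.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValidationError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = clean_sequence(str(entry.seq), kind, id=entry.id)
        records.append(SequenceRecord(id=entry.id, seq=seq, kind=kind))
    if not records:
        raise ValidationError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


_LABEL_NAMES = {0: "negative", 1: "positive", "0": "negative", "1": "positive"}


def read_manifest(path: str | Path) -> list[PairRecord]:
    """Read a TSV pair manifest: ``rna_id<TAB>protein_id[<TAB>label]``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if cols[:2] != ["rna_id", "protein_id"]:
        raise ValidationError(
            f"manifest {path} must start with columns rna_id, protein_id; "
            f"got {cols[:2]}"
        )
    has_label = "label" in cols
    pairs: list[PairRecord] = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        key = (row.rna_id, row.protein_id)
        if key in seen:
            raise ValidationError(f"duplicate pair {key} in manifest {path}")
        seen.add(key)
        label = "unlabeled"
        if has_label and not pd.isna(row.label):
            if row.label not in _LABEL_NAMES:
                raise ValidationError(
                    f"label must be 0 or 1, got {row.label!r} for pair {key}"
                )
            label = _LABEL_NAMES[row.label]
        pairs.append(PairRecord(rna_id=key[0], protein_id=key[1], label=label))
    return pairs


def write_manifest(pairs: list[PairRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rna_id\tprotein_id\tlabel\n")
        for p in pairs:
            lab = {"positive": "1", "negative": "0", "unlabeled": ""}[p.label]
            fh.write(f"{p.rna_id}\t{p.protein_id}\t{lab}\n")


def build_negative_universe(
    rnas: list[SequenceRecord],
    proteins: list[SequenceRecord],
    positives: list[PairRecord],
) -> list[PairRecord]:
    """Full cross product of rna x protein ids minus the positive pairs,
    everything labeled negative.

    For R lncRNAs, P proteins and k distinct positives drawn from the cross
    product this yields R*P - k candidate negatives.
    """
    rna_ids = [r.id for r in rnas]
    prot_ids = [p.id for p in proteins]
    rna_set, prot_set = set(rna_ids), set(prot_ids)
    pos_keys = set()
    for pos in positives:
        if pos.rna_id not in rna_set:
            raise ValidationError(f"positive references unknown RNA {pos.rna_id!r}")
        if pos.protein_id not in prot_set:
            raise ValidationError(
                f"positive references unknown protein {pos.protein_id!r}"
            )
        pos_keys.add((pos.rna_id, pos.protein_id))
    negatives = [
        PairRecord(rna_id=r, protein_id=p, label="negative")
        for r in rna_ids
        for p in prot_ids
        if (r, p) not in pos_keys
    ]
    logger.info(
        "negative universe: %d x %d = %d pairs, %d positives removed -> %d",
        len(rna_ids), len(prot_ids), len(rna_ids) * len(prot_ids),
        len(pos_keys), len(negatives),
    )
    return negatives


def partition_negatives(
    negatives: list[PairRecord],
    subset_size: int,
    seed: int,
    positives: list[PairRecord] | None = None,
) -> BalancedSplit:
    """Randomly partition negatives into floor(N / subset_size) disjoint
    subsets of exactly ``subset_size``, discarding the remainder.

    Sampling is without replacement under ``seed``; the discard count is
    logged so no pair vanishes silently.
    """
    n = len(negatives)
    if subset_size < 1:
        raise ValidationError("subset_size must be >= 1")
    if subset_size > n:
        raise ValidationError(
            f"subset_size {subset_size} exceeds negative count {n}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_subsets = n // subset_size
    discarded = n - n_subsets * subset_size
    subsets = [
        [negatives[j] for j in order[i * subset_size : (i + 1) * subset_size]]
        for i in range(n_subsets)
    ]
    if discarded:
        logger.warning(
            "partition discarded %d leftover negatives (< subset_size)", discarded
        )
    return BalancedSplit(
        positives=list(positives) if positives else [],
        negative_subsets=subsets,
        subset_size=subset_size,
        n_discarded=discarded,
    )
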