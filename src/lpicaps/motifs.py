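"""Motif-count features: 18 lncRNA motifs + 11 protein motifs = 29 dims.

Counts are raw overlapping-occurrence counts.  RNA patterns may use IUPAC
degeneracy codes; protein patterns are literal residue strings (Y means
tyrosine, not a pyrimidine).  Group motifs sum their members' counts.

The exact pattern set is a shipped, editable config
(``lpicaps/data/motifs.yaml``); the 18+11 layout and ordering are the
fixed contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from lpicaps.io_dataset import SequenceRecord

#: IUPAC nucleotide degeneracy over the RNA alphabet
IUPAC_RNA: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"), "Y": frozenset("CU"), "S": frozenset("CG"),
    "W": frozenset("AU"), "K": frozenset("GU"), "M": frozenset("AC"),
    "B": frozenset("CGU"), "D": frozenset("AGU"), "H": frozenset("ACU"),
    "V": frozenset("ACG"), "N": frozenset("ACGU"),
}

RNA_MOTIF_DIM = 18
PROTEIN_MOTIF_DIM = 11
PAIR_MOTIF_DIM = RNA_MOTIF_DIM + PROTEIN_MOTIF_DIM  # 29


@dataclass(frozen=True)
class MotifDef:
    name: str
    target: str  # "rna" | "protein"
    patterns: tuple[str, ...] = ()
    group_members: tuple[str, ...] = ()

    @property
    def is_group(self) -> bool:
        return bool(self.group_members)


@dataclass
class MotifTable:
    """Ordered motif definitions; the order fixes the feature layout."""

    rna: list[MotifDef]
    protein: list[MotifDef]

    def __post_init__(self) -> None:
        if len(self.rna) != RNA_MOTIF_DIM:
            raise ValueError(f"expected {RNA_MOTIF_DIM} RNA motifs, got {len(self.rna)}")
        if len(self.protein) != PROTEIN_MOTIF_DIM:
            raise ValueError(
                f"expected {PROTEIN_MOTIF_DIM} protein motifs, got {len(self.protein)}"
            )
        for defs, codes in ((self.rna, IUPAC_RNA), (self.protein, None)):
            byname = {m.name: m for m in defs}
            for m in defs:
                if m.is_group:
                    missing = [g for g in m.group_members if g not in byname]
                    if missing:
                        raise ValueError(f"group {m.name!r} references unknown {missing}")
                elif not m.patterns:
                    raise ValueError(f"motif {m.name!r} has no patterns")
                if codes is not None:
                    for pat in m.patterns:
                        bad = set(pat) - set(codes)
                        if bad:
                            raise ValueError(
                                f"RNA motif {m.name!r} pattern {pat!r} has "
                                f"non-IUPAC symbols {sorted(bad)}"
                            )

    def names(self) -> list[str]:
        return [m.name for m in self.rna] + [m.name for m in self.protein]


def _parse_entries(entries: list[dict], target: str) -> list[MotifDef]:
    out = []
    for e in entries:
        out.append(
            MotifDef(
                name=str(e["name"]),
                target=target,
                patterns=tuple(str(p) for p in e.get("patterns", [])),
                group_members=tuple(str(g) for g in e.get("group", [])),
            )
        )
    return out


def load_motif_table(path: str | Path | None = None) -> MotifTable:
    """Load a motif table from YAML; with no path, the packaged default."""
    if path is None:
        text = resources.files("lpicaps").joinpath("data/motifs.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return MotifTable(
        rna=_parse_entries(raw["rna"], "rna"),
        protein=_parse_entries(raw["protein"], "protein"),
    )


def _count_pattern(seq: str, pattern: str, degenerate: bool) -> int:
    """Overlapping occurrences of one pattern.

    Unknown residues in the sequence (N/X) never match, not even against
    the degenerate code N -- an unobserved base is not evidence of a motif.
    """
    m = len(pattern)
    if m == 0 or m > len(seq):
        return 0
    if degenerate:
        sets = [IUPAC_RNA[ch] for ch in pattern]
        return sum(
            all(seq[i + j] in sets[j] for j in range(m))
            for i in range(len(seq) - m + 1)
        )
    return sum(seq.startswith(pattern, i) for i in range(len(seq) - m + 1))


def count_motif(seq: str, motif: MotifDef, table: MotifTable | None = None) -> int:
    """Total overlapping occurrences over all patterns of ``motif``.

    A group motif's count is the sum of its members' counts; resolving a
    group requires the owning ``table``.
    """
    if motif.is_group:
        if table is None:
            raise ValueError(f"group motif {motif.name!r} requires its table")
        defs = table.rna if motif.target == "rna" else table.protein
        byname = {m.name: m for m in defs}
        return sum(
            count_motif(seq, byname[member], table) for member in motif.group_members
        )
    degenerate = motif.target == "rna"
    return sum(_count_pattern(seq, pat, degenerate) for pat in motif.patterns)


def pair_motif_features(
    rna: SequenceRecord, protein: SequenceRecord, table: MotifTable
) -> np.ndarray:
    """29-dim raw-count vector: [18 RNA motifs | 11 protein motifs]."""
    rna_counts = [count_motif(rna.seq, m, table) for m in table.rna]
    prot_counts = [count_motif(protein.seq, m, table) for m in table.protein]
    return np.array(rna_counts + prot_counts, dtype=float)
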