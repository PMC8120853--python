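"""Fourier-spectrum features over per-residue numeric profiles.

A sequence of length L is mapped to a numeric profile (a physicochemical
property per residue, or a structure indicator), and the profile is
compressed to a fixed number of cosine-series coefficients

    X'_k = sqrt(2/L) * sum_{n=0}^{L-1} X_n cos[(pi/L)(n+1/2)(k+1/2)]

for k = 0..9 -- a DCT-IV-type transform.  Ten terms per profile give a
length-independent encoding: 2 RNA + 8 protein property tables yield the
100-dim physicochemical vector, and the paired/unpaired RNA indicator plus
the state-propensity protein profile yield the 20-dim structure vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from lpicaps.io_dataset import PROTEIN_ALPHABET, RNA_ALPHABET, SequenceRecord
from lpicaps.structure import CHOU_FASMAN, ProteinStructure, RnaStructure

N_SPECTRUM_TERMS = 10
#: fixed table order defining the physicochemical feature layout
RNA_TABLE_ORDER = ("vdw", "hbond")
PROTEIN_TABLE_ORDER = (
    "bull_breese",
    "kyte_doolittle",
    "zimmerman_polarity",
    "grantham_polarity",
    "isoelectric_point",
    "bulkiness",
    "eisenberg",
    "hopp_woods",
)
PAIR_PHYSCHEM_DIM = (len(RNA_TABLE_ORDER) + len(PROTEIN_TABLE_ORDER)) * N_SPECTRUM_TERMS
PAIR_STRUCTURE_DIM = 2 * N_SPECTRUM_TERMS


@dataclass(frozen=True)
class PropertyTable:
    """One named residue -> value mapping for RNA or protein."""

    name: str
    target: str  # "rna" | "protein"
    values: dict

    def __post_init__(self) -> None:
        alphabet = RNA_ALPHABET if self.target == "rna" else PROTEIN_ALPHABET
        missing = set(alphabet) - set(self.values)
        if missing:
            raise ValueError(
                f"property table {self.name!r} missing residues {sorted(missing)}"
            )
        if not all(np.isfinite(v) for v in self.values.values()):
            raise ValueError(f"non-finite value in property table {self.name!r}")


def load_property_tables(path: str | Path | None = None) -> dict[str, PropertyTable]:
    """Load residue property tables from TSV (default: packaged tables)."""
    if path is None:
        text = (
            resources.files("lpicaps").joinpath("data/property_tables.tsv").read_text()
        )
    else:
        text = Path(path).read_text()
    raw: dict[str, tuple[str, dict]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        table, target, residue, value = line.split("\t")
        name_target, values = raw.setdefault(table, (target, {}))
        if name_target != target:
            raise ValueError(f"table {table!r} mixes targets")
        values[residue] = float(value)
    return {
        name: PropertyTable(name=name, target=target, values=values)
        for name, (target, values) in raw.items()
    }


def numeric_profile(seq: str, table: PropertyTable) -> np.ndarray:
    """Element-wise property lookup; unknown residues map to 0.0."""
    unknown = [ch for ch in set(seq) if ch not in table.values]
    if unknown:
        warnings.warn(
            f"residues {sorted(unknown)} absent from table {table.name!r} "
            "mapped to 0.0",
            stacklevel=2,
        )
    return np.array([table.values.get(ch, 0.0) for ch in seq])


def structure_profile(struct: RnaStructure) -> np.ndarray:
    """Binary pairing indicator: 1 at paired positions, 0 at unpaired."""
    return np.array([0.0 if ch == "." else 1.0 for ch in struct.pairing])


def protein_structure_profile(struct: ProteinStructure) -> np.ndarray:
    """Each residue's Chou-Fasman propensity for its predicted state
    (P_helix if H, P_sheet if E, P_turn if C)."""
    state_idx = {"H": 0, "E": 1, "C": 2}
    return np.array(
        [
            CHOU_FASMAN.get(aa, (1.0, 1.0, 1.0))[state_idx[st]]
            for aa, st in zip(struct.seq, struct.states)
        ]
    )


def fourier_spectrum(profile: np.ndarray, terms: int = N_SPECTRUM_TERMS) -> np.ndarray:
    """First ``terms`` cosine-series coefficients of a numeric profile.

    The spectrum length is always ``terms`` regardless of L; for L < terms
    the sum simply runs over the available positions.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or profile.size == 0:
        raise ValueError("profile must be a non-empty 1-D vector")
    L = profile.size
    n = np.arange(L)
    k = np.arange(terms)
    basis = np.cos((np.pi / L) * np.outer(k + 0.5, n + 0.5))
    return np.sqrt(2.0 / L) * (basis @ profile)


def pair_physchem_features(
    rna: SequenceRecord,
    protein: SequenceRecord,
    tables: dict[str, PropertyTable],
) -> np.ndarray:
    """100-dim physicochemical spectrum vector: 2 RNA + 8 protein tables,
    10 terms each, in the fixed table order."""
    blocks = []
    for name in RNA_TABLE_ORDER + PROTEIN_TABLE_ORDER:
        if name not in tables:
            raise ValueError(f"missing property table {name!r}")
        table = tables[name]
        seq = rna.seq if table.target == "rna" else protein.seq
        blocks.append(fourier_spectrum(numeric_profile(seq, table)))
    return np.concatenate(blocks)


def pair_structure_features(
    rna_struct: RnaStructure, prot_struct: ProteinStructure
) -> np.ndarray:
    """20-dim secondary-structure spectrum vector: [RNA pairing spectrum |
    protein state-propensity spectrum]."""
    return np.concatenate(
        [
            fourier_spectrum(structure_profile(rna_struct)),
            fourier_spectrum(protein_structure_profile(prot_struct)),
        ]
    )
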