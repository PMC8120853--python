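"""Assembly of the four per-pair feature channels.

Every channel's pair vector is a concatenation of an RNA block and a
protein block, so blocks are computed once per sequence and cached; a pair
lookup is then a cheap concatenation.  A fingerprint over the channel
layout and the motif/property configuration is stored with trained models
so a model refuses to score features produced under a different config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from lpicaps import kmer, motifs, spectral, structure
from lpicaps.io_dataset import PairRecord, SequenceRecord

#: channel short names and their fixed dimensions
CHANNEL_DIMS = {"SF": 320, "Mtf": 29, "PC": 100, "SS": 20}
CHANNELS = tuple(CHANNEL_DIMS)


@dataclass
class FeatureBundle:
    """The four fixed-dimension feature vectors for one pair."""

    sf: np.ndarray
    mtf: np.ndarray
    pc: np.ndarray
    ss: np.ndarray

    def __post_init__(self) -> None:
        for name, vec in self.as_dict().items():
            want = CHANNEL_DIMS[name]
            if vec.shape != (want,):
                raise ValueError(
                    f"channel {name} has shape {vec.shape}, expected ({want},)"
                )

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"SF": self.sf, "Mtf": self.mtf, "PC": self.pc, "SS": self.ss}

    def concatenated(self, channels: tuple[str, ...] = CHANNELS) -> np.ndarray:
        d = self.as_dict()
        return np.concatenate([d[c] for c in channels])


class FeaturePipeline:
    """Featurizes sequences and pairs under a fixed configuration.

    Parameters
    ----------
    motif_table:
        Motif definitions (default: the packaged 18+11 table).
    property_tables:
        Residue property tables (default: the packaged 2 RNA + 8 protein
        tables plus the Chou-Fasman propensities used for the structure
        channel).
    channels:
        Enabled channel subset, in canonical order; disabled channels are
        simply absent from the output, mirroring closing a subnet channel.
    rna_folder:
        Callable seq -> RnaStructure (default: built-in Nussinov folding).
    protein_folder:
        Callable seq -> ProteinStructure (default: Chou-Fasman scan).
    """

    def __init__(
        self,
        motif_table: motifs.MotifTable | None = None,
        property_tables: dict[str, spectral.PropertyTable] | None = None,
        channels: tuple[str, ...] = CHANNELS,
        rna_folder=structure.nussinov_fold,
        protein_folder=structure.chou_fasman_states,
    ) -> None:
        bad = [c for c in channels if c not in CHANNEL_DIMS]
        if bad:
            raise ValueError(f"unknown channels {bad}; valid: {list(CHANNEL_DIMS)}")
        if not channels:
            raise ValueError("at least one feature channel must be enabled")
        self.channels = tuple(c for c in CHANNELS if c in channels)
        self.motif_table = motif_table or motifs.load_motif_table()
        self.property_tables = property_tables or spectral.load_property_tables()
        self.rna_folder = rna_folder
        self.protein_folder = protein_folder
        self._rna_cache: dict[str, dict[str, np.ndarray]] = {}
        self._prot_cache: dict[str, dict[str, np.ndarray]] = {}

    # -- per-sequence blocks ------------------------------------------------

    def _rna_blocks(self, rec: SequenceRecord) -> dict[str, np.ndarray]:
        blocks = self._rna_cache.get(rec.id)
        if blocks is not None:
            return blocks
        blocks = {}
        if "SF" in self.channels:
            blocks["SF"] = kmer.kmer_frequencies(
                rec.seq, kmer.RNA_K, "ACGU"
            ).values
        if "Mtf" in self.channels:
            blocks["Mtf"] = np.array(
                [
                    motifs.count_motif(rec.seq, m, self.motif_table)
                    for m in self.motif_table.rna
                ],
                dtype=float,
            )
        if "PC" in self.channels:
            blocks["PC"] = np.concatenate(
                [
                    spectral.fourier_spectrum(
                        spectral.numeric_profile(rec.seq, self.property_tables[name])
                    )
                    for name in spectral.RNA_TABLE_ORDER
                ]
            )
        if "SS" in self.channels:
            folded = self.rna_folder(rec.seq)
            blocks["SS"] = spectral.fourier_spectrum(
                spectral.structure_profile(folded)
            )
        self._rna_cache[rec.id] = blocks
        return blocks

    def _prot_blocks(self, rec: SequenceRecord) -> dict[str, np.ndarray]:
        blocks = self._prot_cache.get(rec.id)
        if blocks is not None:
            return blocks
        blocks = {}
        if "SF" in self.channels:
            blocks["SF"] = kmer.kmer_frequencies(
                kmer.reduce_protein(rec.seq), kmer.PROTEIN_K, kmer.REDUCED_ALPHABET
            ).values
        if "Mtf" in self.channels:
            blocks["Mtf"] = np.array(
                [
                    motifs.count_motif(rec.seq, m, self.motif_table)
                    for m in self.motif_table.protein
                ],
                dtype=float,
            )
        if "PC" in self.channels:
            blocks["PC"] = np.concatenate(
                [
                    spectral.fourier_spectrum(
                        spectral.numeric_profile(rec.seq, self.property_tables[name])
                    )
                    for name in spectral.PROTEIN_TABLE_ORDER
                ]
            )
        if "SS" in self.channels:
            folded = self.protein_folder(rec.seq)
            blocks["SS"] = spectral.fourier_spectrum(
                spectral.protein_structure_profile(folded)
            )
        self._prot_cache[rec.id] = blocks
        return blocks

    # -- public API ---------------------------------------------------------

    def featurize_pair(
        self, rna: SequenceRecord, protein: SequenceRecord
    ) -> FeatureBundle:
        """Full four-channel bundle for one pair (requires all channels)."""
        if self.channels != CHANNELS:
            raise ValueError("featurize_pair requires all four channels enabled")
        r, p = self._rna_blocks(rna), self._prot_blocks(protein)
        return FeatureBundle(
            sf=np.concatenate([r["SF"], p["SF"]]),
            mtf=np.concatenate([r["Mtf"], p["Mtf"]]),
            pc=np.concatenate([r["PC"], p["PC"]]),
            ss=np.concatenate([r["SS"], p["SS"]]),
        )

    def featurize_pairs(
        self,
        rnas: list[SequenceRecord],
        proteins: list[SequenceRecord],
        pairs: list[PairRecord],
    ) -> dict[str, np.ndarray]:
        """Channel name -> (n_pairs, channel_dim) matrix for enabled channels."""
        rna_by_id = {r.id: r for r in rnas}
        prot_by_id = {p.id: p for p in proteins}
        missing = [
            (p.rna_id, p.protein_id)
            for p in pairs
            if p.rna_id not in rna_by_id or p.protein_id not in prot_by_id
        ]
        if missing:
            raise ValueError(f"manifest references unknown ids: {missing[:5]}")
        out = {c: [] for c in self.channels}
        for pair in pairs:
            r = self._rna_blocks(rna_by_id[pair.rna_id])
            p = self._prot_blocks(prot_by_id[pair.protein_id])
            for c in self.channels:
                out[c].append(np.concatenate([r[c], p[c]]))
        return {c: np.vstack(rows) for c, rows in out.items()}

    def fingerprint(self) -> str:
        """Stable hash over channel layout and feature configuration."""
        payload = {
            "channels": list(self.channels),
            "dims": {c: CHANNEL_DIMS[c] for c in self.channels},
            "motifs": [
                [m.name, list(m.patterns), list(m.group_members)]
                for m in self.motif_table.rna + self.motif_table.protein
            ],
            "properties": {
                name: sorted(t.values.items())
                for name, t in sorted(self.property_tables.items())
            },
        }
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()
        return digest[:16]
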