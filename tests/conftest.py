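import numpy as np
import pytest

from lpicaps.io_dataset import PairRecord, SequenceRecord


@pytest.fixture
def rna_record():
    return SequenceRecord(id="r1", seq="ACGUACGUACGUGGGAAACCC", kind="rna")


@pytest.fixture
def protein_record():
    return SequenceRecord(id="p1", seq="MKDEHRKFILAAGSTWYQNCV", kind="protein")


@pytest.fixture
def small_fasta(tmp_path):
    """Write tiny FASTA + manifest inputs; returns their paths."""
    rna = tmp_path / "rna.fasta"
    rna.write_text(">r1\nACGTACGTACGT\n>r2\nGGGAAACCCAAA\n>r3\nAUAUAUAUAUAU\n")
    prot = tmp_path / "protein.fasta"
    prot.write_text(">p1\nMKDEHRKFILAA\n>p2\nGGGGGGGGGGGG\n")
    manifest = tmp_path / "pairs.tsv"
    manifest.write_text(
        "rna_id\tprotein_id\tlabel\n"
        "r1\tp1\t1\n"
        "r2\tp1\t0\n"
        "r3\tp2\t0\n"
    )
    return rna, prot, manifest


def random_records(rng, n_rna=4, n_prot=3, rna_len=30, prot_len=25):
    rnas = [
        SequenceRecord(
            id=f"r{i}",
            seq="".join(rng.choice(list("ACGU"), size=rna_len)),
            kind="rna",
        )
        for i in range(n_rna)
    ]
    prots = [
        SequenceRecord(
            id=f"p{i}",
            seq="".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=prot_len)),
            kind="protein",
        )
        for i in range(n_prot)
    ]
    return rnas, prots


@pytest.fixture
def random_pair():
    rng = np.random.default_rng(42)
    rnas, prots = random_records(rng, n_rna=1, n_prot=1, rna_len=60, prot_len=50)
    return rnas[0], prots[0]
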