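"""Secondary-structure prediction for lncRNAs and proteins.

The built-in predictors keep the whole pipeline runnable with no external
installs: a maximum-base-pair Nussinov dynamic program for RNA (Watson-
Crick + GU wobble, minimum hairpin loop of 3) and a classical Chou-Fasman
propensity scan for proteins.  Adapters can shell out to RNAfold (true
minimum-free-energy folding) or Predator where those tools are installed.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass

import numpy as np

try:  # pure-python fallback keeps the module importable without a JIT
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (a and callable(a[0])) else a[0]


@dataclass(frozen=True)
class RnaStructure:
    """Dot-bracket pairing string aligned to the RNA sequence."""

    seq: str
    pairing: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.pairing):
            raise ValueError("pairing string length != sequence length")
        depth = 0
        for ch in self.pairing:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise ValueError("unbalanced dot-bracket string")
            elif ch != ".":
                raise ValueError(f"illegal structure character {ch!r}")
        if depth != 0:
            raise ValueError("unbalanced dot-bracket string")

    @property
    def n_pairs(self) -> int:
        return self.pairing.count("(")


@dataclass(frozen=True)
class ProteinStructure:
    """Per-residue H (helix) / E (strand) / C (coil) state string."""

    seq: str
    states: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.states):
            raise ValueError("state string length != sequence length")
        bad = set(self.states) - set("HEC")
        if bad:
            raise ValueError(f"illegal protein states {sorted(bad)}")


# --------------------------------------------------------------------------
# Nussinov maximum-base-pair folding

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}
# Watson-Crick + GU wobble; row/col order A,C,G,U.  Unknown base = -1,
# never pairs.
_PAIR_OK = np.array(
    [
        [0, 0, 0, 1],
        [0, 0, 1, 0],
        [0, 1, 0, 1],
        [1, 0, 1, 0],
    ],
    dtype=np.int8,
)


@njit(cache=False)
def _nussinov_fill(enc: np.ndarray, min_loop: int) -> np.ndarray:
    n = enc.shape[0]
    M = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i + 1, j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if enc[i] >= 0 and enc[k] >= 0 and _PAIR_OK[enc[i], enc[k]]:
                    inner = M[i + 1, k - 1] if k - 1 > i + 1 else 0
                    right = M[k + 1, j] if k + 1 <= j else 0
                    cand = 1 + inner + right
                    if cand > best:
                        best = cand
            M[i, j] = best
    return M


def nussinov_fold(seq: str, min_loop: int = 3) -> RnaStructure:
    """Maximum-base-pair nested structure with a hairpin-loop constraint.

    Ties are broken deterministically: leave the 5'-most base unpaired when
    that loses nothing, otherwise pair it with the smallest admissible
    partner index.
    """
    if not seq:
        raise ValueError("empty RNA sequence")
    enc = np.array([_BASE_INDEX.get(ch, -1) for ch in seq], dtype=np.int64)
    n = len(seq)
    M = _nussinov_fill(enc, min_loop)
    struct = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop or M[i, j] == 0:
            continue
        if M[i, j] == M[i + 1, j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + min_loop + 1, j + 1):
            if enc[i] >= 0 and enc[k] >= 0 and _PAIR_OK[enc[i], enc[k]]:
                inner = M[i + 1, k - 1] if k - 1 > i + 1 else 0
                right = M[k + 1, j] if k + 1 <= j else 0
                if M[i, j] == 1 + inner + right:
                    struct[i], struct[k] = "(", ")"
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    break
    return RnaStructure(seq=seq, pairing="".join(struct))


# --------------------------------------------------------------------------
# Chou-Fasman protein secondary structure

#: classical Chou-Fasman conformational propensities (helix, sheet, turn),
#: scaled so 1.0 is the indifferent value
CHOU_FASMAN: dict[str, tuple[float, float, float]] = {
    "A": (1.42, 0.83, 0.66), "R": (0.98, 0.93, 0.95), "N": (0.67, 0.89, 1.56),
    "D": (1.01, 0.54, 1.46), "C": (0.70, 1.19, 1.19), "Q": (1.11, 1.10, 0.98),
    "E": (1.51, 0.37, 0.74), "G": (0.57, 0.75, 1.56), "H": (1.00, 0.87, 0.95),
    "I": (1.08, 1.60, 0.47), "L": (1.21, 1.30, 0.59), "K": (1.14, 0.74, 1.01),
    "M": (1.45, 1.05, 0.60), "F": (1.13, 1.38, 0.60), "P": (0.57, 0.55, 1.52),
    "S": (0.77, 0.75, 1.43), "T": (0.83, 1.19, 0.96), "W": (1.08, 1.37, 0.96),
    "Y": (0.69, 1.47, 1.14), "V": (1.06, 1.70, 0.50),
}
# unknown residue X: indifferent in all states
_CF_UNKNOWN = (1.0, 1.0, 1.0)

_H_NUC_WIN, _H_NUC_MIN = 6, 4  # helix: >=4 formers in a window of 6
_E_NUC_WIN, _E_NUC_MIN = 5, 3  # sheet: >=3 formers in a window of 5
_EXT_WIN = 4  # extension continues while a 4-residue edge window averages > 1


def _propensities(seq: str, state: int) -> np.ndarray:
    return np.array([CHOU_FASMAN.get(aa, _CF_UNKNOWN)[state] for aa in seq])


def _nucleate_and_extend(p: np.ndarray, win: int, need: int) -> np.ndarray:
    """Mark residues covered by a nucleation window, then extend each
    region outward while the trailing 4-residue window averages > 1."""
    n = len(p)
    mask = np.zeros(n, dtype=bool)
    formers = p >= 1.0
    for i in range(n - win + 1):
        if formers[i : i + win].sum() >= need:
            mask[i : i + win] = True
    if not mask.any():
        return mask
    # extend each maximal run outward
    changed = True
    while changed:
        changed = False
        for i in range(n):
            if mask[i]:
                continue
            # extend rightward: window ending at i
            lo = max(0, i - _EXT_WIN + 1)
            if i > 0 and mask[i - 1] and p[lo : i + 1].mean() > 1.0:
                mask[i] = True
                changed = True
                continue
            hi = min(n, i + _EXT_WIN)
            if i + 1 < n and mask[i + 1] and p[i:hi].mean() > 1.0:
                mask[i] = True
                changed = True
    return mask


def chou_fasman_states(seq: str) -> ProteinStructure:
    """Classical Chou-Fasman scan: nucleate helix/sheet windows, extend
    bidirectionally, resolve overlaps by the higher mean propensity, and
    leave everything else coil."""
    n = len(seq)
    if n == 0:
        raise ValueError("empty protein sequence")
    ph = _propensities(seq, 0)
    pe = _propensities(seq, 1)
    helix = _nucleate_and_extend(ph, _H_NUC_WIN, _H_NUC_MIN)
    sheet = _nucleate_and_extend(pe, _E_NUC_WIN, _E_NUC_MIN)
    states = np.full(n, "C", dtype="<U1")
    states[helix] = "H"
    states[sheet] = "E"
    both = helix & sheet
    if both.any():
        # resolve each overlapping run as a block by mean propensity
        i = 0
        while i < n:
            if both[i]:
                j = i
                while j < n and both[j]:
                    j += 1
                states[i:j] = "H" if ph[i:j].mean() >= pe[i:j].mean() else "E"
                i = j
            else:
                i += 1
    return ProteinStructure(seq=seq, states="".join(states))


# --------------------------------------------------------------------------
# External tool adapters

class ExternalToolError(RuntimeError):
    pass


def external_structure_adapter(
    seq, tool: str, path: str | None = None
) -> RnaStructure | ProteinStructure:
    """Run RNAfold or Predator on one record and parse its stdout.

    The adapters are optional: when the executable is missing, the error
    names the built-in predictor to use instead.
    """
    if tool == "rnafold":
        exe = path or "RNAfold"
        fallback = "nussinov_fold"
    elif tool == "predator":
        exe = path or "predator"
        fallback = "chou_fasman_states"
    else:
        raise ValueError(f"unknown tool {tool!r}")
    if shutil.which(exe) is None:
        raise ExternalToolError(
            f"{exe!r} not found on PATH; use the built-in predictor "
            f"lpicaps.structure.{fallback} instead"
        )
    if tool == "rnafold":
        proc = subprocess.run(
            [exe, "--noPS"],
            input=f">{seq.id}\n{seq.seq}\n",
            capture_output=True,
            text=True,
            check=True,
        )
        return _parse_rnafold(seq.seq, proc.stdout)
    proc = subprocess.run(
        [exe], input=seq.seq, capture_output=True, text=True, check=True
    )
    return _parse_hec(seq.seq, proc.stdout)


def _parse_rnafold(seq: str, out: str) -> RnaStructure:
    for line in out.splitlines():
        line = line.strip()
        if line and set(line.split()[0]) <= set("().,"):
            pairing = line.split()[0].replace(",", ".")
            if len(pairing) != len(seq):
                raise ExternalToolError(
                    f"RNAfold structure length {len(pairing)} != sequence "
                    f"length {len(seq)}; output was: {line[:80]!r}"
                )
            return RnaStructure(seq=seq, pairing=pairing)
    raise ExternalToolError(f"no dot-bracket line in RNAfold output: {out[:200]!r}")


def _parse_hec(seq: str, out: str) -> ProteinStructure:
    for line in out.splitlines():
        line = line.strip().upper()
        if line and set(line) <= set("HEC"):
            if len(line) != len(seq):
                raise ExternalToolError(
                    f"state string length {len(line)} != sequence length {len(seq)}"
                )
            return ProteinStructure(seq=seq, states=line)
    raise ExternalToolError(f"no H/E/C line in tool output: {out[:200]!r}")
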