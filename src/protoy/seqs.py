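"""Nucleotide-sequence primitives shared across the package.

All coordinates in this package are 0-based half-open. Sequences are plain
uppercase ``str`` objects; numpy uint8 views are used internally where speed
matters.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
from Bio.Seq import Seq

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# uint8 complement lookup for vectorised read simulation
_COMP_LUT = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTNacgtn", b"TGCANtgcan"):
    _COMP_LUT[_a] = _b


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMP)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp_array(arr: np.ndarray) -> np.ndarray:
    return _COMP_LUT[arr][::-1]


def random_seq(rng: np.random.Generator, n: int,
               freqs: Sequence[float] | None = None) -> str:
    """I.i.d. random sequence of length ``n`` with base frequencies ``freqs``
    (order A, C, G, T; default uniform)."""
    if n <= 0:
        return ""
    p = None if freqs is None else np.asarray(freqs, dtype=float)
    if p is not None:
        p = p / p.sum()
    codes = rng.choice(4, size=n, p=p)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return array_to_seq(bases[codes])


_NON_STOP_CODONS = tuple(
    a + b + c
    for a in BASES for b in BASES for c in BASES
    if a + b + c not in STOP_CODONS
)


def random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """Random complete open reading frame of ``n_codons`` codons in total,
    beginning with ATG and ending with TAA, no internal stop."""
    if n_codons < 3:
        raise ValueError("an ORF needs at least start, one internal and stop codon")
    internal = rng.choice(len(_NON_STOP_CODONS), size=n_codons - 2)
    return "ATG" + "".join(_NON_STOP_CODONS[i] for i in internal) + "TAA"


def is_complete_orf(seq: str) -> bool:
    """True iff ``seq`` starts with ATG, ends with a stop codon, has no
    internal stop and a length divisible by three."""
    if len(seq) < 9 or len(seq) % 3 != 0:
        return False
    if not seq.startswith("ATG") or seq[-3:] not in STOP_CODONS:
        return False
    return all(seq[i:i + 3] not in STOP_CODONS for i in range(3, len(seq) - 3, 3))


def translate(seq: str) -> str:
    """Standard-code translation (delegates to biopython)."""
    return str(Seq(seq).translate())


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return int(np.count_nonzero(seq_to_array(a) != seq_to_array(b)))


def synonymous_site(rng: np.random.Generator, orf: str,
                    exclude_codons: Sequence[int] = ()) -> tuple[int, str]:
    """Pick a random (position, alternative base) inside ``orf`` such that the
    substitution is synonymous under the standard code and creates no stop.

    Returns the 0-based position on the ORF and the replacement base.
    """
    n_codons = len(orf) // 3
    excluded = set(exclude_codons) | {0, n_codons - 1}
    order = rng.permutation(n_codons)
    for ci in order:
        ci = int(ci)
        if ci in excluded:
            continue
        codon = orf[ci * 3:ci * 3 + 3]
        aa = translate(codon)
        offsets = rng.permutation(3)
        for off in offsets:
            off = int(off)
            for base in BASES:
                if base == codon[off]:
                    continue
                alt = codon[:off] + base + codon[off + 1:]
                if alt in STOP_CODONS:
                    continue
                if translate(alt) == aa:
                    return ci * 3 + off, base
    raise RuntimeError("no synonymous site available")
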