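"""Insertion borders and transposition signatures (TIR / TSD).

The locus insertion interval is found by aligning the M-contig against its
non-M homolog: the maximal interval present only on the M-contig, bounded by
high-identity flank matches. Two transposition signatures are then tested:
terminal inverted repeats (best local alignment between the insertion's two
end windows, one reverse-complemented) and a target-site duplication (a short
direct repeat flanking the insertion that occurs as a single copy at the
homologous junction of the non-M contig).

Coordinate dialect: the insertion interval includes exactly one of the two
TSD motif copies (the right one), so deleting the interval from the M-contig
reproduces the non-M contig exactly.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

from Bio import Align

from .selfalign import MatchSegment, cross_align
from .seqs import revcomp

Interval = tuple[int, int]


class BordersUndeterminableError(ValueError):
    """No homologous flank found on one or both sides of the M-contig."""


@dataclass(frozen=True)
class TIREvidence:
    left: Interval           # on the insertion sequence
    right: Interval          # forward coordinates of the reverse-complement match
    identity: float
    length: int


@dataclass(frozen=True)
class TSDEvidence:
    motif: str
    length: int
    left_pos: int            # start of the left motif copy on the M-contig
    right_pos: int           # start of the right motif copy on the M-contig
    non_m_pos: int           # single-copy position on the non-M contig
    verified: bool


@dataclass
class InsertionCall:
    interval: Interval                  # on the M-contig
    left_flank: MatchSegment | None
    right_flank: MatchSegment | None
    identical: bool = False
    ambiguity: int = 0                  # overlap of the flank images on the non-M contig
    tir: TIREvidence | None = None
    tsd: TSDEvidence | None = None

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]

    def to_dict(self) -> dict:
        d = {"interval": list(self.interval), "length": self.length,
             "identical": self.identical, "ambiguity": self.ambiguity,
             "tir": None if self.tir is None else asdict(self.tir),
             "tsd": None if self.tsd is None else asdict(self.tsd)}
        for key, seg in (("left_flank", self.left_flank),
                         ("right_flank", self.right_flank)):
            d[key] = None if seg is None else asdict(seg)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)


def find_insertion(m_contig: str, non_m_contig: str, min_flank: int = 500,
                   k: int = 50, max_gap: int = 50) -> InsertionCall:
    """Locate the interval present only on the M-contig.

    Flanks are anchored with the k-mer chaining engine in cross-contig mode.
    The left flank is the forward segment starting leftmost on the M-contig,
    the right flank the one ending rightmost; when their images on the non-M
    contig overlap (the target-site duplication situation) the insertion is
    extended rightwards by the overlap so it contains exactly one motif copy,
    and the overlap width is reported as the placement ambiguity.
    """
    segs = [s for s in cross_align(m_contig, non_m_contig, k=k,
                                   min_seg_len=min_flank, max_gap=max_gap)
            if s.strand == "+"]
    if not segs:
        raise BordersUndeterminableError(
            "borders undeterminable: no homologous flank match")
    left = min(segs, key=lambda s: (s.qstart, -s.qend))
    right = max(segs, key=lambda s: (s.qend, -s.qstart))
    if left == right:
        if m_contig == non_m_contig:
            n = len(m_contig)
            return InsertionCall((n, n), left, right, identical=True)
        raise BordersUndeterminableError(
            "borders undeterminable: flank match on one side only")
    if left.qend > right.qstart:
        raise BordersUndeterminableError(
            "borders undeterminable: flank matches overlap on the M-contig")
    ov = max(0, left.tend - right.tstart)
    return InsertionCall((left.qend, right.qstart + ov), left, right,
                         ambiguity=ov)


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -4
    return aligner


def detect_tir(insertion_seq: str, window: int = 300, min_len: int = 10,
               min_identity: float = 80.0) -> TIREvidence | None:
    """Best local alignment between the first ``window`` bp of the insertion
    and the reverse complement of its last ``window`` bp; reported when the
    aligned length reaches ``min_len`` at ``min_identity`` percent identity."""
    n = len(insertion_seq)
    if n < 2 * window:
        raise ValueError("insertion shorter than two windows")
    left = insertion_seq[:window]
    right_rc = revcomp(insertion_seq[-window:])
    alns = _local_aligner().align(left, right_rc)
    if len(alns) == 0:
        return None
    aln = alns[0]
    qblocks, tblocks = aln.aligned
    if len(qblocks) == 0:
        return None
    matches = 0
    aligned_cols = 0
    for (qs, qe), (ts, te) in zip(qblocks, tblocks):
        matches += sum(1 for a, b in zip(left[qs:qe], right_rc[ts:te]) if a == b)
        aligned_cols += qe - qs
    # count gap columns between blocks
    for i in range(1, len(qblocks)):
        aligned_cols += (qblocks[i][0] - qblocks[i - 1][1]) + \
                        (tblocks[i][0] - tblocks[i - 1][1])
    identity = 100.0 * matches / aligned_cols
    q0, q1 = int(qblocks[0][0]), int(qblocks[-1][1])
    t0, t1 = int(tblocks[0][0]), int(tblocks[-1][1])
    length = max(q1 - q0, t1 - t0)
    if length < min_len or identity < min_identity:
        return None
    # map the right-window coordinates back to forward insertion coordinates
    right_iv = (n - t1, n - t0)
    return TIREvidence((q0, q1), right_iv, identity, length)


def detect_tsd(m_contig: str, insertion: Interval, non_m_contig: str,
               left_flank: MatchSegment,
               len_range: tuple[int, int] = (2, 20)) -> TSDEvidence | None:
    """Search for a target-site duplication flanking the insertion.

    For L from the top of ``len_range`` down, tests whether the L-mer
    immediately left of the insertion equals the L-mer ending at the
    insertion's right edge (the insertion contains the right motif copy as its
    suffix under this package's dialect); on success the motif is verified to
    occur as a single copy at the homologous junction of the non-M contig,
    located through the left flank's coordinates. Returns the longest verified
    L (or the longest unverified candidate if none verifies)."""
    s, e = insertion
    lo, hi = len_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid len_range")
    diag = left_flank.tstart - left_flank.qstart  # non-M pos = M pos + diag
    fallback: TSDEvidence | None = None
    for L in range(hi, lo - 1, -1):
        if s - L < 0 or e - L < s:
            continue
        left_mer = m_contig[s - L:s]
        right_mer = m_contig[e - L:e]
        if left_mer != right_mer:
            continue
        j = s + diag  # homologous junction on the non-M contig
        verified = (
            0 <= j - L and j <= len(non_m_contig)
            and non_m_contig[j - L:j] == left_mer
            and non_m_contig[j:j + L] != left_mer
            and non_m_contig[max(0, j - 2 * L):j - L] != left_mer
        )
        ev = TSDEvidence(left_mer, L, s - L, e - L, j - L, verified)
        if verified:
            return ev
        if fallback is None:
            fallback = ev
    return fallback


def classify_signature(call: InsertionCall) -> str:
    """Deterministic transposition-signature label from the evidence fields."""
    has_tir = call.tir is not None
    has_tsd = call.tsd is not None and call.tsd.verified
    if has_tir and has_tsd:
        return "transposon-like"
    if has_tsd:
        return "TSD-only"
    if has_tir:
        return "TIR-only"
    return "none"


def characterize_insertion(m_contig: str, non_m_contig: str,
                           min_flank: int = 500, k: int = 50,
                           tir_window: int = 300, tir_min_len: int = 10,
                           tir_min_identity: float = 80.0,
                           tsd_len_range: tuple[int, int] = (2, 20)
                           ) -> tuple[InsertionCall, str]:
    """find_insertion + detect_tir + detect_tsd + classify_signature."""
    call = find_insertion(m_contig, non_m_contig, min_flank=min_flank, k=k)
    s, e = call.interval
    ins_seq = m_contig[s:e]
    if len(ins_seq) >= 2 * tir_window:
        call.tir = detect_tir(ins_seq, window=tir_window, min_len=tir_min_len,
                              min_identity=tir_min_identity)
    if call.left_flank is not None and not call.identical:
        call.tsd = detect_tsd(m_contig, call.interval, non_m_contig,
                              call.left_flank, len_range=tsd_len_range)
    return call, classify_signature(call)
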