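"""Self-alignment dotplot engine and structural callers.

The engine finds maximal chained runs of shared k-mers between a sequence and
itself (or between two sequences), on both strands, the way a dotplot is
computed: seeds on the same diagonal (forward) or anti-diagonal (reverse
complement) are chained when the unmatched stretch between them is at most
``max_gap``. Segment identity is then recomputed by global edit-distance
re-alignment of the called intervals (seed density under-estimates identity).

On top of the segments sit three structural callers: palindromes (inverted
arm pairs around a spacer), tandem-duplication clusters, and gene-copy
enumeration with intact/truncated classification.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import edlib
import numpy as np

from .seqs import is_complete_orf, revcomp

Interval = tuple[int, int]


@dataclass(frozen=True)
class MatchSegment:
    """A chained similarity segment between query and target intervals.

    For strand '-', the target interval is given in forward coordinates of the
    reverse-complement match (query[qstart:qend] ~ revcomp(target[tstart:tend])).
    """
    qstart: int
    qend: int
    tstart: int
    tend: int
    strand: str
    identity: float


@dataclass(frozen=True)
class PalindromeCall:
    arm1: Interval
    arm2: Interval
    spacer: Interval
    arm_length: int
    identity: float

    @property
    def spacer_length(self) -> int:
        return self.spacer[1] - self.spacer[0]


@dataclass(frozen=True)
class GeneCopy:
    interval: Interval       # on the contig
    strand: str
    gene_interval: Interval  # matched subinterval of the gene
    identity: float
    intact: bool


@dataclass(frozen=True)
class TandemCluster:
    interval: Interval
    n_members: int
    period: float
    orientation: dict


def realign_identity(a: str, b: str) -> float:
    """Percent identity from a global edit-distance alignment of a vs b."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 100.0 * (1.0 - d / max(len(a), len(b)))


# ---------------------------------------------------------------------------
# seeding and chaining
# ---------------------------------------------------------------------------

def _kmer_index(seq: str, k: int) -> dict[bytes, np.ndarray]:
    b = seq.encode("ascii")
    idx: dict[bytes, list[int]] = {}
    for i in range(len(b) - k + 1):
        idx.setdefault(b[i:i + k], []).append(i)
    return {key: np.asarray(v, dtype=np.int64) for key, v in idx.items()}


def seed_matches(query: str, target: str, k: int, *, self_mode: bool = False
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All exact k-mer matches of query against target, both strands.

    Returns (fwd_q, fwd_t, rev_q, rev_t) position arrays. In ``self_mode`` the
    trivial identity diagonal is excluded and the symmetric duplicate of each
    match is dropped (canonical order: query position <= target position).
    """
    idx = _kmer_index(target, k)
    qb = query.encode("ascii")
    rc = revcomp(query).encode("ascii")
    n = len(query)

    fq_pos, fq_hits, rq_pos, rq_hits = [], [], [], []
    for i in range(n - k + 1):
        hits = idx.get(qb[i:i + k])
        if hits is not None:
            fq_pos.append(i)
            fq_hits.append(hits)
        hits = idx.get(rc[n - i - k:n - i])
        if hits is not None:
            rq_pos.append(i)
            rq_hits.append(hits)

    def gather(pos: list[int], hit_lists: list[np.ndarray]):
        if not pos:
            e = np.empty(0, dtype=np.int64)
            return e, e.copy()
        counts = [len(h) for h in hit_lists]
        qs = np.repeat(np.asarray(pos, dtype=np.int64), counts)
        ts = np.concatenate(hit_lists)
        return qs, ts

    fq, ft = gather(fq_pos, fq_hits)
    rq, rt = gather(rq_pos, rq_hits)
    if self_mode:
        keep = fq < ft
        fq, ft = fq[keep], ft[keep]
        keep = rq <= rt
        rq, rt = rq[keep], rt[keep]
    return fq, ft, rq, rt


def _chain(qs: np.ndarray, ts: np.ndarray, k: int, max_gap: int,
           strand: str) -> list[tuple[int, int, int, int]]:
    """Chain collinear seeds; returns (qstart, qend, tstart, tend) tuples."""
    if len(qs) == 0:
        return []
    key = (ts - qs) if strand == "+" else (qs + ts)
    order = np.lexsort((qs, key))
    q, t, kd = qs[order], ts[order], key[order]
    brk = np.empty(len(q), dtype=bool)
    brk[0] = True
    brk[1:] = (kd[1:] != kd[:-1]) | (q[1:] - q[:-1] - k > max_gap)
    starts = np.flatnonzero(brk)
    ends = np.r_[starts[1:], len(q)]
    out = []
    for s, e in zip(starts, ends):
        q0, q1 = int(q[s]), int(q[e - 1]) + k
        if strand == "+":
            t0, t1 = int(t[s]), int(t[e - 1]) + k
        else:
            t0, t1 = int(t[e - 1]), int(t[s]) + k
        out.append((q0, q1, t0, t1))
    return out


def _make_segments(query: str, target: str, chains_f, chains_r,
                   min_seg_len: int) -> list[MatchSegment]:
    segs = []
    for q0, q1, t0, t1 in chains_f:
        if q1 - q0 < min_seg_len:
            continue
        ident = realign_identity(query[q0:q1], target[t0:t1])
        segs.append(MatchSegment(q0, q1, t0, t1, "+", ident))
    for q0, q1, t0, t1 in chains_r:
        if q1 - q0 < min_seg_len:
            continue
        ident = realign_identity(query[q0:q1], revcomp(target[t0:t1]))
        segs.append(MatchSegment(q0, q1, t0, t1, "-", ident))
    segs.sort(key=lambda s: (s.qstart, s.tstart, s.strand))
    return segs


def cross_align(query: str, target: str, k: int = 15,
                min_seg_len: int | None = None, max_gap: int = 50
                ) -> list[MatchSegment]:
    """Dotplot segments between two different sequences."""
    if k < 8:
        raise ValueError("k must be >= 8")
    if len(query) < k or len(target) < k:
        return []
    if min_seg_len is None:
        min_seg_len = 2 * k
    fq, ft, rq, rt = seed_matches(query, target, k)
    return _make_segments(query, target,
                          _chain(fq, ft, k, max_gap, "+"),
                          _chain(rq, rt, k, max_gap, "-"),
                          min_seg_len)


def self_align(seq: str, k: int = 15, min_seg_len: int | None = None,
               max_gap: int = 50) -> list[MatchSegment]:
    """Dotplot segments of a sequence against itself, both strands, identity
    diagonal excluded, each symmetric pair represented once (qstart <= tstart)."""
    if k < 8:
        raise ValueError("k must be >= 8")
    if len(seq) < k:
        return []
    if min_seg_len is None:
        min_seg_len = 2 * k
    fq, ft, rq, rt = seed_matches(seq, seq, k, self_mode=True)
    return _make_segments(seq, seq,
                          _chain(fq, ft, k, max_gap, "+"),
                          _chain(rq, rt, k, max_gap, "-"),
                          min_seg_len)


# ---------------------------------------------------------------------------
# palindromes
# ---------------------------------------------------------------------------

def detect_palindrome(segments: Sequence[MatchSegment], seq: str,
                      min_arm: int = 200, min_identity: float = 80.0,
                      center_tol: int = 100) -> list[PalindromeCall]:
    """Call palindromes from reverse-strand self-alignment segments.

    Reverse segments with disjoint intervals are grouped by their
    anti-diagonal (mirror centre) with single-linkage tolerance
    ``center_tol``; each group's query side becomes arm 1 and target side
    arm 2, realigned (arm1 vs revcomp(arm2)) for identity. Calls are returned
    longest-arm first; the spacer is the gap between the arms.
    """
    # keep reverse segments whose intervals are in mirror order; a spacer-less
    # palindrome's single segment overlaps itself around the centre, so full
    # disjointness is only required after the centre split below
    rev = [s for s in segments
           if s.strand == "-" and s.qstart < s.tstart and s.qend < s.tend]
    if not rev:
        return []
    rev.sort(key=lambda s: s.qstart + s.tend)
    groups: list[list[MatchSegment]] = [[rev[0]]]
    for seg in rev[1:]:
        prev = groups[-1][-1]
        if (seg.qstart + seg.tend) - (prev.qstart + prev.tend) <= center_tol:
            groups[-1].append(seg)
        else:
            groups.append([seg])

    calls = []
    for group in groups:
        a1 = (min(s.qstart for s in group), max(s.qend for s in group))
        a2 = (min(s.tstart for s in group), max(s.tend for s in group))
        if a1[1] > a2[0]:
            # arms of a spacer-less palindrome overlap around the hairpin
            # centre by up to k-1; split them at the midpoint
            if a1[0] >= a2[0] or a1[1] >= a2[1]:
                continue
            mid = (a1[1] + a2[0]) // 2
            a1 = (a1[0], mid)
            a2 = (mid, a2[1])
        ident = realign_identity(seq[a1[0]:a1[1]], revcomp(seq[a2[0]:a2[1]]))
        arm_len = max(a1[1] - a1[0], a2[1] - a2[0])
        if arm_len < min_arm or ident < min_identity:
            continue
        calls.append(PalindromeCall(a1, a2, (a1[1], a2[0]), arm_len, ident))
    calls.sort(key=lambda c: (-c.arm_length, c.arm1[0]))
    return calls


# ---------------------------------------------------------------------------
# tandem clusters
# ---------------------------------------------------------------------------

def detect_tandem_clusters(segments: Sequence[MatchSegment],
                           min_members: int = 3,
                           cluster_gap: int = 0) -> list[TandemCluster]:
    """Cluster forward off-diagonal segments by single-linkage on the span
    [qstart, tend); clusters with >= min_members are reported with period =
    median offset among near-minimal offsets (offsets <= 1.5 x minimum), which
    estimates the repeat unit spacing rather than a multiple of it."""
    fwd = sorted((s for s in segments if s.strand == "+"),
                 key=lambda s: min(s.qstart, s.tstart))
    if not fwd:
        return []
    clusters: list[list[MatchSegment]] = [[fwd[0]]]
    span_end = max(fwd[0].qend, fwd[0].tend)
    for seg in fwd[1:]:
        lo = min(seg.qstart, seg.tstart)
        if lo <= span_end + cluster_gap:
            clusters[-1].append(seg)
            span_end = max(span_end, seg.qend, seg.tend)
        else:
            clusters.append([seg])
            span_end = max(seg.qend, seg.tend)

    out = []
    rev = [s for s in segments if s.strand == "-"]
    for members in clusters:
        if len(members) < min_members:
            continue
        lo = min(min(s.qstart, s.tstart) for s in members)
        hi = max(max(s.qend, s.tend) for s in members)
        offsets = np.array([abs(s.tstart - s.qstart) for s in members])
        m = offsets.min()
        period = float(np.median(offsets[offsets <= 1.5 * m]))
        n_rev = sum(1 for s in rev
                    if lo <= min(s.qstart, s.tstart) and max(s.qend, s.tend) <= hi)
        out.append(TandemCluster((lo, hi), len(members), period,
                                 {"+": len(members), "-": n_rev}))
    out.sort(key=lambda c: (-(c.interval[1] - c.interval[0]), c.interval[0]))
    return out


# ---------------------------------------------------------------------------
# gene copy enumeration
# ---------------------------------------------------------------------------

def enumerate_gene_copies(contig: str, gene_seq: str, k: int = 10,
                          min_len: int = 200, min_identity: float = 85.0,
                          intact_min_frac: float = 0.99,
                          max_gap: int = 50) -> list[GeneCopy]:
    """Enumerate gene-derived copies on a contig.

    Local matches of the gene against the contig (both strands) are merged
    into one copy when they are continuous on both contig and gene (collinear
    within ``max_gap``); a copy is intact iff its matched gene subinterval
    covers >= intact_min_frac of the gene and the oriented contig sequence is
    a complete ORF. Ties between overlapping merges resolve leftmost-start,
    then longest.
    """
    if not is_complete_orf(gene_seq):
        raise ValueError("gene_seq must be a complete ORF")
    segs = cross_align(gene_seq, contig, k=k,
                       min_seg_len=max(2 * k, 20), max_gap=max_gap)
    segs.sort(key=lambda s: (s.tstart, -s.tend))

    merged: list[dict] = []
    for seg in segs:
        placed = False
        for copy in merged:
            if copy["strand"] != seg.strand:
                continue
            gap_t = seg.tstart - copy["tend"]
            if gap_t < -max_gap or gap_t > max_gap:
                continue
            if seg.strand == "+":
                gap_q = seg.qstart - copy["qend"]
            else:
                gap_q = copy["qstart"] - seg.qend
            if abs(gap_q - gap_t) > max_gap:
                continue
            copy["tend"] = max(copy["tend"], seg.tend)
            copy["qstart"] = min(copy["qstart"], seg.qstart)
            copy["qend"] = max(copy["qend"], seg.qend)
            placed = True
            break
        if not placed:
            merged.append({"tstart": seg.tstart, "tend": seg.tend,
                           "qstart": seg.qstart, "qend": seg.qend,
                           "strand": seg.strand})

    glen = len(gene_seq)
    copies = []
    for c in merged:
        if c["tend"] - c["tstart"] < min_len:
            continue
        sub = contig[c["tstart"]:c["tend"]]
        oriented = sub if c["strand"] == "+" else revcomp(sub)
        ident = realign_identity(oriented, gene_seq[c["qstart"]:c["qend"]])
        if ident < min_identity:
            continue
        covers = (c["qend"] - c["qstart"]) >= intact_min_frac * glen
        intact = bool(covers and is_complete_orf(oriented))
        copies.append(GeneCopy((c["tstart"], c["tend"]), c["strand"],
                               (c["qstart"], c["qend"]), ident, intact))
    copies.sort(key=lambda c: (c.interval[0], -(c.interval[1] - c.interval[0])))
    return copies


def truncated_fraction(contig: str, copies: Sequence[GeneCopy]) -> float:
    """Fraction of contig positions covered by at least one non-intact copy
    interval (union, not sum)."""
    if not contig:
        raise ValueError("empty contig")
    ivs = sorted(c.interval for c in copies if not c.intact)
    covered = 0
    cur_s = cur_e = None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered / len(contig)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

_TSV_HEADER = "qstart\tqend\ttstart\ttend\tstrand\tidentity"


def export_dotplot(segments: Sequence[MatchSegment],
                   tsv_path: str | os.PathLike,
                   plot_path: str | os.PathLike | None = None) -> None:
    """Write segments as TSV (the testable surface) and optionally a raster
    dotplot (forward blue, reverse orange)."""
    with open(tsv_path, "w") as fh:
        fh.write(_TSV_HEADER + "\n")
        for s in segments:
            fh.write(f"{s.qstart}\t{s.qend}\t{s.tstart}\t{s.tend}\t"
                     f"{s.strand}\t{s.identity!r}\n")
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 6))
        for s in segments:
            if s.strand == "+":
                ax.plot([s.qstart, s.qend], [s.tstart, s.tend], color="tab:blue", lw=1)
            else:
                ax.plot([s.qstart, s.qend], [s.tend, s.tstart], color="tab:orange", lw=1)
        ax.set_xlabel("position (bp)")
        ax.set_ylabel("position (bp)")
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)


def read_segments_tsv(path: str | os.PathLike) -> list[MatchSegment]:
    segs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _TSV_HEADER:
            raise ValueError("unrecognised segments TSV header")
        for line in fh:
            q0, q1, t0, t1, strand, ident = line.rstrip("\n").split("\t")
            segs.append(MatchSegment(int(q0), int(q1), int(t0), int(t1),
                                     strand, float(ident)))
    return segs
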