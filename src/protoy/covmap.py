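"""Read placement, per-base depth, hemizygous copy number, M-specific regions.

Copy number of a hemizygous gene is estimated from read depth the way it is
done for young sex loci: mean per-base coverage of the target gene is divided
by the mean coverage of each of three single-copy autosomal reference genes,
the three ratios are averaged, and the result is multiplied by two because
autosomal genes have two alleles while the M-locus is hemizygous.

Male-specific regions are delineated by subtraction: contig positions with
any female coverage are masked, and remaining positions with male depth above
a minimum coverage cutoff are merged into intervals.
"""
from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqs import revcomp_array, seq_to_array

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


# ---------------------------------------------------------------------------
# depth tracks
# ---------------------------------------------------------------------------

@dataclass
class DepthTrack:
    """Per-base read depth over one named sequence (fractional allowed)."""
    name: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.float64)
        if (self.depth < 0).any():
            raise ValueError("negative depth")

    def __len__(self) -> int:
        return len(self.depth)

    def mean(self) -> float:
        return float(self.depth.mean()) if len(self.depth) else 0.0


# ---------------------------------------------------------------------------
# read placement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Placement:
    read: str
    ref: str
    start: int
    length: int
    strand: str
    mismatches: int
    weight: float

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class PlacementSet:
    placements: list[Placement]
    n_reads: int
    n_unplaced: int
    n_skipped: int
    max_mismatches: int
    seed_len: int

    def for_ref(self, name: str) -> list[Placement]:
        return [p for p in self.placements if p.ref == name]


def place_reads(reads: Iterable[tuple[str, str]],
                references: Mapping[str, str],
                max_mismatches: int = 2,
                seed_len: int = 31) -> PlacementSet:
    """Place reads on references by exact k-mer seeding plus verification.

    Each read receives all equally best substitution-only placements (both
    strands) with at most ``max_mismatches`` mismatches; multi-placed reads
    carry weight 1/(number of best placements), which is deterministic and
    unbiased for coverage sums. Seeds are taken at ``max_mismatches + 1``
    evenly spaced read offsets, so any qualifying placement contains at least
    one exact seed (pigeonhole). Reads shorter than the seed are skipped and
    counted.
    """
    if not references:
        raise ValueError("references must be non-empty")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    s = seed_len
    ref_names = list(references)
    ref_arrays = [seq_to_array(references[n]) for n in ref_names]
    index: dict[bytes, list[tuple[int, int]]] = {}
    for ri, name in enumerate(ref_names):
        b = references[name].encode("ascii")
        for i in range(len(b) - s + 1):
            index.setdefault(b[i:i + s], []).append((ri, i))

    placements: list[Placement] = []
    n_reads = n_unplaced = n_skipped = 0
    for read_name, seq in reads:
        n_reads += 1
        L = len(seq)
        if L < s:
            n_skipped += 1
            continue
        n_chunks = max_mismatches + 1
        offs = sorted({min(int(j * L / n_chunks), L - s) for j in range(n_chunks)})
        fwd = seq_to_array(seq)
        rev = revcomp_array(fwd)
        fb = fwd.tobytes()
        rb = rev.tobytes()
        cands: set[tuple[int, int, str]] = set()
        for o in offs:
            for key, arr in ((fb[o:o + s], "+"), (rb[o:o + s], "-")):
                for ri, p in index.get(key, ()):
                    start = p - o
                    if 0 <= start <= len(ref_arrays[ri]) - L:
                        cands.add((ri, start, arr))
        best = None
        hits: list[tuple[int, int, str, int]] = []
        for ri, start, strand in cands:
            arr = fwd if strand == "+" else rev
            mism = int(np.count_nonzero(ref_arrays[ri][start:start + L] != arr))
            if mism > max_mismatches:
                continue
            if best is None or mism < best:
                best = mism
                hits = [(ri, start, strand, mism)]
            elif mism == best:
                hits.append((ri, start, strand, mism))
        if not hits:
            n_unplaced += 1
            continue
        w = 1.0 / len(hits)
        for ri, start, strand, mism in sorted(hits):
            placements.append(Placement(read_name, ref_names[ri], start, L,
                                        strand, mism, w))
    if n_skipped:
        logger.warning("%d reads shorter than seed length %d were skipped",
                       n_skipped, s)
    return PlacementSet(placements, n_reads, n_unplaced, n_skipped,
                        max_mismatches, s)


def compute_depth(placements: PlacementSet | Sequence[Placement],
                  ref_name: str, ref_len: int) -> DepthTrack:
    """Per-base depth: depth[i] = sum of weights of placements covering i."""
    plist = placements.placements if isinstance(placements, PlacementSet) else placements
    diff = np.zeros(ref_len + 1, dtype=np.float64)
    for p in plist:
        if p.ref != ref_name:
            continue
        if p.start < 0 or p.end > ref_len:
            raise ValueError("placement outside reference")
        diff[p.start] += p.weight
        diff[p.end] -= p.weight
    depth = np.cumsum(diff[:-1])
    # fractional weights leave ~1e-16 residue after summation; clamp it
    depth[(depth < 0) & (depth > -1e-9)] = 0.0
    return DepthTrack(ref_name, depth)


# ---------------------------------------------------------------------------
# samtools-depth dialect TSV
# ---------------------------------------------------------------------------

def _fmt_depth(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else f"{v:.4f}"


def write_depth_tsv(track: DepthTrack, path: str | os.PathLike,
                    omit_zeros: bool = True) -> None:
    """TAB-separated "name, 1-based position, depth" rows; zero-depth rows
    optionally omitted. Fractional depths use fixed precision 4."""
    with open(path, "w") as fh:
        for i, v in enumerate(track.depth):
            if omit_zeros and v == 0:
                continue
            fh.write(f"{track.name}\t{i + 1}\t{_fmt_depth(v)}\n")


def read_depth_tsv(path: str | os.PathLike, name: str | None = None,
                   length: int | None = None) -> DepthTrack:
    """Parse the samtools-depth dialect back into a track. ``length`` is
    required for lossless round-trips when zero rows were omitted (defaults to
    the largest position seen)."""
    rows: list[tuple[int, float]] = []
    seen_name = name
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}: malformed line {lineno}: expected 3 fields")
            nm, pos_s, depth_s = fields
            if name is not None and nm != name:
                continue
            try:
                pos = int(pos_s)
                depth = float(depth_s)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from None
            if pos < 1 or (length is not None and pos > length):
                raise ValueError(f"{path}: line {lineno}: position {pos} out of bounds")
            if depth < 0:
                raise ValueError(f"{path}: line {lineno}: negative depth")
            if seen_name is None:
                seen_name = nm
            elif nm != seen_name:
                raise ValueError(
                    f"{path}: line {lineno}: multiple sequence names; pass name=")
            rows.append((pos, depth))
    n = length if length is not None else (max((p for p, _ in rows), default=0))
    depth = np.zeros(n, dtype=np.float64)
    for pos, v in rows:
        depth[pos - 1] = v
    return DepthTrack(seen_name or "unknown", depth)


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------

@dataclass
class CopyNumberEstimate:
    """Three-reference-normalised, x2-corrected copy number of a target gene.

    ``copy_number = 2 * mean(target_mean / ref_mean over the three reference
    genes)``; the factor two corrects for hemizygosity of the target against
    diploid single-copy references.
    """
    target: str
    target_mean: float
    ref_means: dict[str, float]
    ratios: dict[str, float]
    mean_ratio: float
    copy_number: float
    female_mean: float | None = None

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "target_mean_coverage": self.target_mean,
            "reference_mean_coverage": self.ref_means,
            "relative_coverage": self.ratios,
            "mean_relative_coverage": self.mean_ratio,
            "copy_number": self.copy_number,
            "female_background_mean": self.female_mean,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)


def estimate_copy_number(target_track: DepthTrack,
                         ref_tracks: Sequence[DepthTrack],
                         female_target_track: DepthTrack | None = None
                         ) -> CopyNumberEstimate:
    if len(ref_tracks) != 3:
        raise ValueError("exactly three reference tracks are required")
    tmean = target_track.mean()
    ref_means = {t.name: t.mean() for t in ref_tracks}
    for nm, m in ref_means.items():
        if m == 0:
            raise ValueError(f"reference {nm!r} has zero mean depth "
                             "(broken reference choice)")
    ratios = {nm: tmean / m for nm, m in ref_means.items()}
    mean_ratio = sum(ratios.values()) / len(ratios)
    return CopyNumberEstimate(
        target=target_track.name,
        target_mean=tmean,
        ref_means=ref_means,
        ratios=ratios,
        mean_ratio=mean_ratio,
        copy_number=2.0 * mean_ratio,
        female_mean=None if female_target_track is None else female_target_track.mean(),
    )


@dataclass(frozen=True)
class BackgroundCheck:
    female_mean: float
    male_mean: float
    threshold_frac: float
    negligible: bool


def female_background_check(female_target_track: DepthTrack,
                            male_target_track: DepthTrack,
                            threshold_frac: float = 0.05) -> BackgroundCheck:
    """Off-target (e.g. paralog-driven) female coverage over the target gene;
    negligible iff strictly below ``threshold_frac`` of the male target mean."""
    fmean = female_target_track.mean()
    mmean = male_target_track.mean()
    return BackgroundCheck(fmean, mmean, threshold_frac,
                           bool(fmean < threshold_frac * mmean))


# ---------------------------------------------------------------------------
# M-specific regions
# ---------------------------------------------------------------------------

@dataclass
class MSpecificResult:
    intervals: list[Interval]
    masked_positions: np.ndarray
    min_cov: float
    mask_threshold: float | None
    merge_gap: int


def mask_female_covered(female_track: DepthTrack,
                        mask_threshold: float = 1) -> np.ndarray:
    """Positions with female depth >= mask_threshold (sorted array)."""
    if mask_threshold < 1:
        raise ValueError("mask_threshold must be >= 1")
    return np.flatnonzero(female_track.depth >= mask_threshold)


def male_specific_intervals(male_track: DepthTrack,
                            mask: np.ndarray | Sequence[int],
                            min_cov: float = 5,
                            merge_gap: int = 0,
                            mask_threshold: float | None = None
                            ) -> MSpecificResult:
    """Unmasked positions with male depth >= min_cov, merged into maximal
    intervals allowing gaps <= merge_gap; gaps containing a masked position
    are never bridged (no interval may overlap the mask)."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    n = len(male_track)
    maskbool = np.zeros(n, dtype=bool)
    mask = np.asarray(mask, dtype=np.int64)
    if len(mask):
        maskbool[mask] = True
    ok = (male_track.depth >= min_cov) & ~maskbool

    intervals: list[Interval] = []
    idx = np.flatnonzero(ok)
    if len(idx):
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.r_[idx[0], idx[breaks + 1]]
        ends = np.r_[idx[breaks] + 1, idx[-1] + 1]
        runs = list(zip(starts.tolist(), ends.tolist()))
        merged = [runs[0]]
        for s, e in runs[1:]:
            ps, pe = merged[-1]
            if s - pe <= merge_gap and not maskbool[pe:s].any():
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        intervals = merged
    return MSpecificResult(intervals, np.flatnonzero(maskbool), float(min_cov),
                           mask_threshold, merge_gap)


# ---------------------------------------------------------------------------
# presence patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Section:
    start: int
    end: int
    labels: frozenset[str]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PresencePattern:
    """Partition of a contig's covered portion into maximal sections labeled
    by the subset of datasets covering them."""
    sections: list[Section]

    def table(self) -> list[dict]:
        return [{"labels": sorted(s.labels), "start": s.start, "end": s.end,
                 "length": s.length} for s in self.sections]


def _merge_intervals(ivs: Sequence[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for s, e in sorted(ivs):
        if s >= e:
            continue
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def classify_presence_patterns(
        interval_sets: Mapping[str, Sequence[Interval]]) -> PresencePattern:
    """Partition the contig into maximal runs with a constant covering-subset
    label from >= 2 datasets of intervals on the same coordinates."""
    if len(interval_sets) < 2:
        raise ValueError("need interval sets from at least two datasets")
    merged = {name: _merge_intervals(ivs) for name, ivs in interval_sets.items()}
    bounds = sorted({x for ivs in merged.values() for iv in ivs for x in iv})
    sections: list[Section] = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        labels = frozenset(name for name, ivs in merged.items()
                           if any(a <= s and e <= b for a, b in ivs))
        if not labels:
            continue
        if sections and sections[-1].end == s and sections[-1].labels == labels:
            sections[-1] = Section(sections[-1].start, e, labels)
        else:
            sections.append(Section(s, e, labels))
    return PresencePattern(sections)
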