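"""Consensus building and divergent-site counting across intact gene copies.

Intact ORF copies of the male-determining gene from different M-loci are
aligned column-wise, a majority consensus is drawn, each copy's mismatching
columns are listed as divergent sites, and every substitution is classified
synonymous/nonsynonymous under the standard genetic code by translating the
consensus codon with and without the observed base.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

from Bio import Align

from .seqs import STOP_CODONS, translate
from .selfalign import realign_identity


@dataclass(frozen=True)
class DivergentSite:
    position: int            # 0-based on the consensus
    consensus_base: str
    observed_base: str
    codon_index: int
    synonymous: bool | None = None
    creates_stop: bool = False


@dataclass
class CopyDivergence:
    name: str
    sites: list[DivergentSite]

    @property
    def count(self) -> int:
        return len(self.sites)


@dataclass
class ConsensusReport:
    consensus: str
    records: list[CopyDivergence]
    dropped_columns: list[int] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {r.name: r.count for r in self.records}

    def to_dict(self) -> dict:
        return {"consensus_length": len(self.consensus),
                "dropped_columns": self.dropped_columns,
                "records": [{"name": r.name, "count": r.count,
                             "sites": [asdict(s) for s in r.sites]}
                            for r in self.records]}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    return aligner


def _align_to(reference: str, seq: str) -> str:
    """Project ``seq`` onto reference columns via global alignment; positions
    of the reference with no aligned base become '-'."""
    if len(seq) == len(reference):
        return seq
    aln = _global_aligner().align(reference, seq)[0]
    out = ["-"] * len(reference)
    rblocks, qblocks = aln.aligned
    for (rs, re), (qs, qe) in zip(rblocks, qblocks):
        for off in range(re - rs):
            out[rs + off] = seq[qs + off]
    return "".join(out)


def build_consensus(seqs: Sequence[str], min_pairwise_identity: float = 95.0
                    ) -> tuple[str, list[int]]:
    """Per-column majority consensus of >= 2 high-identity ORFs.

    Unequal lengths are aligned to the longest input before voting. Ties are
    broken toward the base of the first input (or, if the first input is not
    among the tied bases, toward the earliest input that is). Columns with a
    gap majority are dropped and their indices reported.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            ident = realign_identity(seqs[i], seqs[j])
            if ident < min_pairwise_identity:
                raise ValueError(
                    f"inputs {i} and {j} are only {ident:.1f}% identical "
                    f"(need >= {min_pairwise_identity}%)")
    longest = max(seqs, key=len)
    cols = [_align_to(longest, s) for s in seqs]

    consensus_chars: list[str] = []
    dropped: list[int] = []
    for pos in range(len(longest)):
        column = [c[pos] for c in cols]
        counts: dict[str, int] = {}
        for b in column:
            counts[b] = counts.get(b, 0) + 1
        best = max(counts.values())
        tied = {b for b, n in counts.items() if n == best}
        pick = next(b for b in column if b in tied)  # first-input tie-break
        if pick == "-":
            dropped.append(pos)
        else:
            consensus_chars.append(pick)
    return "".join(consensus_chars), dropped


def count_divergent_sites(orf: str, consensus: str) -> list[DivergentSite]:
    """Every column where the copy differs from the consensus (position 0-based
    on the consensus; alignment-projected if lengths differ; gap columns are
    not counted — only nucleotide differences)."""
    projected = _align_to(consensus, orf)
    sites = []
    for pos, (c, o) in enumerate(zip(consensus, projected)):
        if o != "-" and o != c:
            sites.append(DivergentSite(pos, c, o, pos // 3))
    return sites


def classify_substitutions(sites: Sequence[DivergentSite], consensus: str
                           ) -> list[DivergentSite]:
    """Fill synonymous flags by codon translation of consensus vs observed."""
    if len(consensus) % 3:
        raise ValueError("consensus length must be a multiple of three")
    out = []
    for site in sites:
        ci = site.codon_index
        codon = consensus[ci * 3:ci * 3 + 3]
        if len(codon) < 3:
            raise ValueError("site outside consensus codons")
        off = site.position % 3
        variant = codon[:off] + site.observed_base + codon[off + 1:]
        creates_stop = variant in STOP_CODONS and codon not in STOP_CODONS \
            and ci != len(consensus) // 3 - 1
        syn = translate(variant) == translate(codon)
        out.append(DivergentSite(site.position, site.consensus_base,
                                 site.observed_base, ci, syn, creates_stop))
    return out


def consensus_report(named_seqs: Sequence[tuple[str, str]]) -> ConsensusReport:
    """Build the consensus over all inputs and report per-copy divergent sites
    with synonymous classification."""
    names = [n for n, _ in named_seqs]
    seqs = [s for _, s in named_seqs]
    consensus, dropped = build_consensus(seqs)
    records = []
    for name, seq in zip(names, seqs):
        sites = classify_substitutions(count_divergent_sites(seq, consensus),
                                       consensus)
        records.append(CopyDivergence(name, sites))
    return ConsensusReport(consensus, records, dropped)


def write_divergence_tsv(report: ConsensusReport, path: str) -> None:
    """Per-copy TSV: name, count, then one row per site (0-based and 1-based
    positions, bases, codon, synonymous flag)."""
    with open(path, "w") as fh:
        fh.write("name\tcount\tposition0\tposition1\tconsensus\tobserved\t"
                 "codon_index\tsynonymous\tcreates_stop\n")
        for rec in report.records:
            if not rec.sites:
                fh.write(f"{rec.name}\t0\t.\t.\t.\t.\t.\t.\t.\n")
            for s in rec.sites:
                fh.write(f"{rec.name}\t{rec.count}\t{s.position}\t{s.position + 1}"
                         f"\t{s.consensus_base}\t{s.observed_base}\t{s.codon_index}"
                         f"\t{s.synonymous}\t{s.creates_stop}\n")
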