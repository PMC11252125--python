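"""Synthetic proto-Y genomes with one hemizygous M-locus, plus ground truth.

The generator emulates the structural situation of a young male-determining
locus: a diploid genome in which males carry a single hemizygous M-locus
(palindromic two-copy or tandem-array architecture of a male-determining
gene), females carry none, three single-copy autosomal reference genes are
present for depth normalisation, and uniform-coverage reads are drawn with a
configurable substitution error rate. Every stochastic operation takes an
explicit seed; identical inputs yield byte-identical genomes, reads and truth
JSON.

Coordinates are 0-based half-open throughout. Truth fragments are plain
nested dicts wrapped in :class:`TruthRecord`, which round-trips losslessly
through JSON.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .seqs import (BASES, is_complete_orf, random_seq, revcomp, seq_to_array,
                   array_to_seq, _COMP_LUT, synonymous_site)

Interval = tuple[int, int]

DEFAULT_SEED = 42


class ComponentOverflowError(ValueError):
    """A locus component does not fit inside total_len_target."""


# ---------------------------------------------------------------------------
# truth records
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    """Machine-readable ground truth for a generated object.

    Wraps a nested dict of intervals (2-lists), flags and file paths; the
    JSON serialisation is canonical (sorted keys) so identical generation
    parameters produce identical files.
    """
    data: dict

    def to_json(self) -> str:
        return json.dumps(self.data, sort_keys=True, indent=1)

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        return cls(json.loads(text))

    @classmethod
    def load(cls, path: str | os.PathLike) -> "TruthRecord":
        with open(path) as fh:
            return cls.from_json(fh.read())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TruthRecord) and self.data == other.data


_INTERVAL_KEYS = {"interval", "spacer", "gene_interval", "arm1", "arm2",
                  "tsd_left", "tsd_right", "insertion"}
_POSITION_KEYS = {"locus_pos", "non_m_pos", "position"}


def shift_truth(fragment: dict, offset: int) -> dict:
    """Return a copy of a truth fragment with every interval/position shifted
    by ``offset`` (used when a locus is embedded into a larger sequence)."""
    def walk(obj, key=None):
        if isinstance(obj, dict):
            return {k: walk(v, k) for k, v in obj.items()}
        if isinstance(obj, list):
            if key in _INTERVAL_KEYS and len(obj) == 2 and all(
                    isinstance(x, int) for x in obj):
                return [obj[0] + offset, obj[1] + offset]
            return [walk(v, key) for v in obj]
        if key in _POSITION_KEYS and isinstance(obj, int):
            return obj + offset
        return obj
    return walk(fragment)


# ---------------------------------------------------------------------------
# architectures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PalindromeArchitecture:
    """Two inverted intact gene copies around a non-palindromic spacer.

    The locus layout is
    ``TIR + distal repeats + pad + gene(+) + fill | spacer | mirror arm + TIR'``
    where the mirror arm is the exact reverse complement of the left arm and
    the spacer carries a direct terminal repeat at each end. ``intercopy_gap``
    is the distance between the two gene copies (fill + spacer + fill), so
    ``intercopy_gap - spacer_len`` must be non-negative and even.
    """
    gene_seq: str
    spacer_len: int = 3046
    spacer_terminal_repeat: str = "CAGTGCTAAGTTACGGATTCGCAGAA"
    intercopy_gap: int = 4700
    tir_seq: str = "GGCCAGTCACAATGGGCGTTTACAGGTG"
    tsd_motif: str = "TTTTAGGTT"
    distal_repeat_unit: str = ""
    distal_repeat_count: int = 0
    total_len_target: int | None = None
    arm_substitutions: int = 1

    def validate(self) -> None:
        if not is_complete_orf(self.gene_seq):
            raise ValueError("gene_seq must be a complete ORF")
        if self.spacer_len < 0:
            raise ValueError("spacer_len must be >= 0")
        if not 2 <= len(self.tsd_motif) <= 50:
            raise ValueError("tsd_motif length must be in [2, 50]")
        if self.distal_repeat_count < 0:
            raise ValueError("distal_repeat_count must be >= 0")
        if self.distal_repeat_count and not self.distal_repeat_unit:
            raise ValueError("distal_repeat_unit empty but count > 0")
        gap = self.intercopy_gap - self.spacer_len
        if gap < 0 or gap % 2:
            raise ValueError("intercopy_gap - spacer_len must be even and >= 0")
        if 0 < self.spacer_len < 2 * len(self.spacer_terminal_repeat):
            raise ValueError("spacer too short for its terminal repeats")
        if self.arm_substitutions < 0:
            raise ValueError("arm_substitutions must be >= 0")


@dataclass(frozen=True)
class TandemArrayArchitecture:
    """Head-to-tail array of gene copies, most of them truncated.

    Truncated copies retain a seeded random subinterval of the gene whose
    length is a fraction in [truncation_min_frac, truncation_max_frac] of the
    gene length and at least ``min_copy_len`` bp. ``intervening_frac`` is the
    target fraction of the locus that is non-gene sequence; intervening gaps
    are unique random filler, optionally salted with repeat units from
    ``intervening_units``.
    """
    gene_seq: str
    n_copies: int
    n_intact: int = 1
    truncation_min_frac: float = 0.1
    truncation_max_frac: float = 0.9
    intervening_units: tuple[str, ...] = ()
    intervening_frac: float = 0.45
    min_copy_len: int = 300
    intact_indices: tuple[int, ...] | None = None
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        if not is_complete_orf(self.gene_seq):
            raise ValueError("gene_seq must be a complete ORF")
        if not 1 <= self.n_intact <= self.n_copies:
            raise ValueError("need 1 <= n_intact <= n_copies")
        if not 0 < self.truncation_min_frac <= self.truncation_max_frac < 1:
            raise ValueError("need 0 < truncation_min_frac <= truncation_max_frac < 1")
        if not 0 <= self.intervening_frac < 1:
            raise ValueError("intervening_frac must be in [0, 1)")
        if self.min_copy_len > int(self.truncation_max_frac * len(self.gene_seq)):
            raise ValueError("min_copy_len exceeds the maximum truncated length")
        if self.intact_indices is not None:
            if len(self.intact_indices) != self.n_intact or not all(
                    0 <= i < self.n_copies for i in self.intact_indices):
                raise ValueError("intact_indices inconsistent with n_copies/n_intact")


@dataclass(frozen=True)
class GenomeBlueprint:
    """Parametric description of a synthetic diploid genome with one M-locus
    and three single-copy autosomal reference genes."""
    chromosomes: tuple[tuple[str, int], ...]
    m_locus_placement: tuple[str, int]
    reference_genes: tuple[tuple[str, str, int, str], ...]  # name, chrom, pos, seq
    background_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    tsd_motif: str = "TTTTAGGTT"
    paralog: tuple[str, str, int, str] | None = None  # name, chrom, pos, seq
    mas_repeat_unit: str = ""
    mas_block_count: int = 0
    mas_chromosomes: tuple[str, ...] = ()
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        lengths = dict(self.chromosomes)
        if len(lengths) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        m_chrom, m_pos = self.m_locus_placement
        if m_chrom not in lengths:
            raise ValueError(f"M-locus chromosome {m_chrom!r} unknown")
        if not 0 <= m_pos <= lengths[m_chrom]:
            raise ValueError("M-locus position out of chromosome bounds")
        if len(self.reference_genes) != 3:
            raise ValueError("exactly three reference genes are required")
        for name, chrom, pos, seq in self.reference_genes:
            if chrom not in lengths:
                raise ValueError(f"reference gene {name!r} on unknown chromosome")
            if chrom == m_chrom:
                raise ValueError(f"reference gene {name!r} on the M chromosome")
            if pos < 0 or pos + len(seq) > lengths[chrom]:
                raise ValueError(f"reference gene {name!r} out of bounds")


@dataclass(frozen=True)
class ReadSimParams:
    read_len: int = 100
    depth: float = 15.0          # fold-coverage per haploid genome copy
    error_rate: float = 0.001    # substitutions per base
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        if self.read_len < 20:
            raise ValueError("read_len must be >= 20")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")


# ---------------------------------------------------------------------------
# locus builders
# ---------------------------------------------------------------------------

def build_palindromic_locus(arch: PalindromeArchitecture,
                            seed: int = DEFAULT_SEED) -> tuple[str, TruthRecord]:
    """Assemble a palindromic two-copy locus and its ground truth.

    The returned truth fragment records every component interval (TIRs, distal
    repeat blocks, gene copies with strand, arm filler, spacer) in locus
    coordinates, plus any substitutions injected between the arms.
    """
    arch.validate()
    rng = np.random.default_rng(seed)
    gene = arch.gene_seq
    fill_len = (arch.intercopy_gap - arch.spacer_len) // 2
    distal = arch.distal_repeat_unit * arch.distal_repeat_count

    fixed = [("tir", len(arch.tir_seq)), ("distal_repeats", len(distal)),
             ("gene_copy", len(gene)), ("arm_fill", fill_len)]
    base_total = 2 * sum(n for _, n in fixed) + arch.spacer_len
    pad_len = 0
    if arch.total_len_target is not None:
        pad_len = (arch.total_len_target - base_total) // 2
        if pad_len < 0:
            running = arch.spacer_len
            for name, n in fixed:
                running += 2 * n
                if running > arch.total_len_target:
                    raise ComponentOverflowError(
                        f"component {name!r} overflows total_len_target="
                        f"{arch.total_len_target} (components need {base_total} bp)")

    pad = random_seq(rng, pad_len)
    fill = random_seq(rng, fill_len)
    if arch.spacer_len == 0:
        spacer = ""
    else:
        rep = arch.spacer_terminal_repeat
        spacer = rep + random_seq(rng, arch.spacer_len - 2 * len(rep)) + rep

    arm1 = arch.tir_seq + distal + pad + gene + fill
    arm2 = revcomp(arm1)
    locus = arm1 + spacer + arm2
    total = len(locus)
    alen = len(arm1)

    # component intervals on arm1, mirrored onto arm2
    comps: list[tuple[str, int, int]] = []
    cursor = 0
    for name, n in [("tir", len(arch.tir_seq)), ("distal_repeats", len(distal)),
                    ("pad", pad_len), ("gene_copy", len(gene)), ("arm_fill", fill_len)]:
        comps.append((name, cursor, cursor + n))
        cursor += n
    mirror = [(name + "_rc", total - e, total - s) for name, s, e in comps]
    gene_iv = next((s, e) for name, s, e in comps if name == "gene_copy")
    gene_iv_rc = (total - gene_iv[1], total - gene_iv[0])

    # optional divergence between the arms: synonymous substitutions in copy 2
    substitutions = []
    locus_arr = bytearray(locus, "ascii")
    used_codons: list[int] = []
    for _ in range(arch.arm_substitutions):
        gpos, alt = synonymous_site(rng, gene, exclude_codons=used_codons)
        used_codons.append(gpos // 3)
        # copy 2 is revcomp(gene); gene position g sits at locus position
        # gene_iv_rc.end - 1 - g carrying the complement base
        lpos = gene_iv_rc[1] - 1 - gpos
        alt_rc = chr(_COMP_LUT[ord(alt)])
        substitutions.append({"locus_pos": lpos, "gene_pos": gpos,
                              "consensus_base": gene[gpos], "base": alt})
        locus_arr[lpos] = ord(alt_rc)
    locus = locus_arr.decode("ascii")

    truth = TruthRecord({
        "kind": "palindrome",
        "length": total,
        "arm1": [0, alen],
        "arm2": [total - alen, total],
        "spacer": [alen, alen + len(spacer)],
        "components": (
            [{"name": n, "interval": [s, e]} for n, s, e in comps]
            + [{"name": "spacer", "interval": [alen, alen + len(spacer)]}]
            + [{"name": n, "interval": [s, e]} for n, s, e in sorted(mirror, key=lambda x: x[1])]
        ),
        "copies": [
            {"interval": list(gene_iv), "strand": "+", "intact": True,
             "gene_interval": [0, len(gene)]},
            {"interval": list(gene_iv_rc), "strand": "-", "intact": True,
             "gene_interval": [0, len(gene)]},
        ],
        "tirs": [{"interval": [0, len(arch.tir_seq)]},
                 {"interval": [total - len(arch.tir_seq), total]}],
        "tsd_motif": arch.tsd_motif,
        "arm_substitutions": substitutions,
    })
    return locus, truth


def build_tandem_array_locus(arch: TandemArrayArchitecture) -> tuple[str, TruthRecord]:
    """Assemble a head-to-tail tandem copy array and its ground truth."""
    arch.validate()
    rng = np.random.default_rng(arch.seed)
    gene = arch.gene_seq
    glen = len(gene)

    if arch.intact_indices is not None:
        intact = set(arch.intact_indices)
    else:
        intact = set(int(i) for i in
                     rng.choice(arch.n_copies, size=arch.n_intact, replace=False))

    lo = max(arch.min_copy_len, int(np.ceil(arch.truncation_min_frac * glen)))
    hi = int(np.floor(arch.truncation_max_frac * glen))
    pieces: list[tuple[int, int]] = []   # gene subinterval per copy
    for i in range(arch.n_copies):
        if i in intact:
            pieces.append((0, glen))
        else:
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, glen - length + 1))
            pieces.append((start, start + length))

    gene_total = sum(e - s for s, e in pieces)
    f = arch.intervening_frac
    non_gene = int(round(gene_total * f / (1.0 - f)))
    n_gaps = arch.n_copies + 1
    if non_gene >= 100 * n_gaps:
        gap_lens = 100 + rng.multinomial(non_gene - 100 * n_gaps,
                                         np.full(n_gaps, 1.0 / n_gaps))
    else:
        gap_lens = rng.multinomial(non_gene, np.full(n_gaps, 1.0 / n_gaps))

    def gap_seq(n: int, j: int) -> str:
        if n <= 0:
            return ""
        if arch.intervening_units and n >= 50 and rng.random() < 0.3:
            unit = arch.intervening_units[j % len(arch.intervening_units)]
            unit = unit[:n]
            filler = random_seq(rng, n - len(unit))
            return unit + filler
        return random_seq(rng, n)

    def patch_gap(g: str, prev_piece, next_piece) -> str:
        # construction guarantee: a gap base adjacent to a copy must not
        # extend the copy's gene homology by chance, or the truth intervals
        # would understate the real maximal matches
        if g and prev_piece is not None and prev_piece[1] < glen:
            want_not = gene[prev_piece[1]]
            if g[0] == want_not:
                g = next(b for b in "ACGT" if b != want_not) + g[1:]
        if g and next_piece is not None and next_piece[0] > 0:
            want_not = gene[next_piece[0] - 1]
            if g[-1] == want_not:
                g = g[:-1] + next(b for b in "ACGT" if b != want_not)
        return g

    parts: list[str] = []
    copies = []
    cursor = 0
    for i in range(arch.n_copies):
        g = gap_seq(int(gap_lens[i]), i)
        g = patch_gap(g, pieces[i - 1] if i else None, pieces[i])
        parts.append(g)
        cursor += len(g)
        s, e = pieces[i]
        sub = gene[s:e]
        copies.append({"interval": [cursor, cursor + len(sub)], "strand": "+",
                       "intact": i in intact, "gene_interval": [s, e]})
        parts.append(sub)
        cursor += len(sub)
    tail = gap_seq(int(gap_lens[-1]), arch.n_copies)
    tail = patch_gap(tail, pieces[-1], None)
    parts.append(tail)
    cursor += len(tail)

    locus = "".join(parts)
    truth = TruthRecord({
        "kind": "tandem_array",
        "length": len(locus),
        "copies": copies,
        "n_copies": arch.n_copies,
        "n_intact": arch.n_intact,
        "gene_total_bases": gene_total,
    })
    return locus, truth


# ---------------------------------------------------------------------------
# insertion with target-site duplication
# ---------------------------------------------------------------------------

@dataclass
class InsertionProduct:
    m_seq: str           # haplotype carrying the insertion
    host_seq: str        # non-M haplotype (single motif copy at the site)
    truth: TruthRecord


def insert_with_tsd(host: str, position: int, insert: str,
                    tsd_motif: str) -> InsertionProduct:
    """Insert ``insert`` into ``host`` at ``position``, duplicating the target
    site motif so it flanks the insert (the transposition signature).

    If the motif is not already present at ``position`` it is first written
    into the host; the returned ``host_seq`` is that single-motif haplotype.
    The truth records both motif copies on the M haplotype, the single-copy
    position on the non-M haplotype, and the insertion interval under the
    dialect "insertion includes the right motif copy", which makes plain
    deletion of the interval reconstruct the host exactly.
    """
    if not insert:
        raise ValueError("empty insert")
    if not tsd_motif:
        raise ValueError("empty tsd_motif")
    if not 0 <= position <= len(host):
        raise ValueError("position out of host bounds")
    m = len(tsd_motif)
    if host[position:position + m] != tsd_motif:
        host = host[:position] + tsd_motif + host[position + m:]
    p = position
    modified = host[:p + m] + insert + tsd_motif + host[p + m:]
    truth = TruthRecord({
        "kind": "insertion",
        "tsd_motif": tsd_motif,
        "tsd_left": [p, p + m],
        "insert_interval": [p + m, p + m + len(insert)],
        "tsd_right": [p + m + len(insert), p + 2 * m + len(insert)],
        "insertion": [p + m, p + 2 * m + len(insert)],
        "non_m_pos": p,
        "host_len": len(host),
        "m_len": len(modified),
    })
    return InsertionProduct(modified, host, truth)


def plant_insertion(host: str, position: int, insert: str,
                    tsd_motif: str) -> InsertionProduct:
    """insert_with_tsd plus a construction guarantee: the planted motif is the
    maximal target-site duplication.

    With a random host there is a ~25% chance per edge that the host base
    immediately left of the site equals the last insert base, or the host base
    following the site equals the first insert base; either coincidence makes
    the true maximal duplication one base longer than the planted motif (the
    truth record would then understate the real TSD, and flank matches would
    shift by one). This helper patches those (at most two) host bases before
    inserting so the planted motif length is exact by construction.
    """
    if not insert:
        raise ValueError("empty insert")
    p = position
    m = len(tsd_motif)
    if p > 0 and host[p - 1] == insert[-1]:
        alt = next(b for b in BASES if b != insert[-1])
        host = host[:p - 1] + alt + host[p:]
    if p + m < len(host) and host[p + m] == insert[0]:
        alt = next(b for b in BASES if b != insert[0])
        host = host[:p + m] + alt + host[p + m + 1:]
    return insert_with_tsd(host, position, insert, tsd_motif)


# ---------------------------------------------------------------------------
# individuals
# ---------------------------------------------------------------------------

Haplotype = dict[str, str]          # chromosome name -> sequence


@dataclass
class Individuals:
    """A male/female pair of synthetic diploid individuals.

    ``male`` maps haplotype names ("A" non-M, "M" M-bearing) to chromosome
    dicts; ``female`` carries two identical non-M haplotypes ("A", "B").
    """
    male: dict[str, Haplotype]
    female: dict[str, Haplotype]
    m_chrom: str
    truth: TruthRecord


def make_individuals(blueprint: GenomeBlueprint, locus_seq: str) -> Individuals:
    """Build the diploid individuals implied by a blueprint: females carry two
    identical non-M haplotypes, males one non-M haplotype plus one haplotype
    with the locus inserted (with TSD) at the blueprint placement."""
    blueprint.validate()
    rng = np.random.default_rng(blueprint.seed)
    lengths = dict(blueprint.chromosomes)
    m_chrom, m_pos = blueprint.m_locus_placement

    base: Haplotype = {}
    planted: dict[str, list[tuple[int, int]]] = {name: [] for name in lengths}
    for name, length in blueprint.chromosomes:
        base[name] = random_seq(rng, length, blueprint.background_composition)

    def plant(chrom: str, pos: int, seq: str, what: str) -> None:
        if pos < 0 or pos + len(seq) > lengths[chrom]:
            raise ValueError(f"{what} out of bounds on {chrom}")
        for s, e in planted[chrom]:
            if pos < e and s < pos + len(seq):
                raise ValueError(f"{what} overlaps a previously planted feature")
        base[chrom] = base[chrom][:pos] + seq + base[chrom][pos + len(seq):]
        planted[chrom].append((pos, pos + len(seq)))

    gene_truth = []
    for name, chrom, pos, seq in blueprint.reference_genes:
        plant(chrom, pos, seq, f"reference gene {name}")
        gene_truth.append({"name": name, "chrom": chrom,
                           "interval": [pos, pos + len(seq)]})
    if blueprint.paralog is not None:
        name, chrom, pos, seq = blueprint.paralog
        plant(chrom, pos, seq, f"paralog {name}")
        gene_truth.append({"name": name, "chrom": chrom,
                           "interval": [pos, pos + len(seq)], "paralog": True})
    if blueprint.mas_repeat_unit and blueprint.mas_block_count:
        block = blueprint.mas_repeat_unit * blueprint.mas_block_count
        for chrom in blueprint.mas_chromosomes:
            plant(chrom, 0, block, "MAS repeat block")
            plant(chrom, lengths[chrom] - len(block), block, "MAS repeat block")

    # single-copy check for reference genes across the whole base haplotype
    genome = "".join(base[name] for name, _ in blueprint.chromosomes)
    for name, _, _, seq in blueprint.reference_genes:
        n = genome.count(seq)
        if n != 1 or locus_seq.count(seq):
            raise ValueError(f"reference gene {name!r} is not single-copy (n={n})")

    for s, e in planted[m_chrom]:
        if m_pos < e and s < m_pos + len(blueprint.tsd_motif):
            raise ValueError("M-locus placement overlaps a planted feature")

    ins = plant_insertion(base[m_chrom], m_pos, locus_seq, blueprint.tsd_motif)
    base[m_chrom] = ins.host_seq               # females carry the motif once
    m_hap = dict(base)
    m_hap[m_chrom] = ins.m_seq

    locus_offset = m_pos + len(blueprint.tsd_motif)
    truth = TruthRecord({
        "kind": "individuals",
        "m_chrom": m_chrom,
        "chromosomes": {name: length for name, length in blueprint.chromosomes},
        "m_hap_len": {name: len(seq) for name, seq in m_hap.items()},
        "reference_genes": gene_truth,
        "insertion": ins.truth.data,
        "locus_interval": [locus_offset, locus_offset + len(locus_seq)],
    })
    return Individuals(
        male={"A": dict(base), "M": m_hap},
        female={"A": dict(base), "B": dict(base)},
        m_chrom=m_chrom,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(haplotypes: Mapping[str, Haplotype],
                   params: ReadSimParams,
                   prefix: str = "read") -> list[tuple[str, str]]:
    """Draw uniform single-end reads from every haplotype.

    Per haplotype the expected per-base depth equals ``params.depth``, so
    diploid regions see twice the per-haplotype rate. Substitution errors are
    applied at ``error_rate`` after strand orientation. Read names encode
    haplotype, chromosome, start and strand for debugging. Deterministic in
    ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    rl = params.read_len
    reads: list[tuple[str, str]] = []
    bases_u8 = np.frombuffer(b"ACGT", dtype=np.uint8)
    code_of = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code_of[b] = i

    for hap in sorted(haplotypes):
        for chrom in sorted(haplotypes[hap]):
            seq = haplotypes[hap][chrom]
            if rl > len(seq):
                raise ValueError(
                    f"read_len {rl} exceeds chromosome {chrom!r} ({len(seq)} bp)")
            n = int(round(params.depth * len(seq) / rl))
            if n == 0:
                continue
            arr = seq_to_array(seq)
            starts = rng.integers(0, len(seq) - rl + 1, size=n)
            strands = rng.integers(0, 2, size=n)
            mat = arr[starts[:, None] + np.arange(rl)]
            rev = np.flatnonzero(strands)
            mat[rev] = _COMP_LUT[mat[rev]][:, ::-1]
            if params.error_rate > 0:
                err = rng.random(mat.shape) < params.error_rate
                if err.any():
                    shift = rng.integers(1, 4, size=int(err.sum())).astype(np.uint8)
                    codes = code_of[mat[err]]
                    mat[err] = bases_u8[(codes + shift) % 4]
            for i in range(n):
                strand = "-" if strands[i] else "+"
                name = f"{prefix}|{hap}|{chrom}|{int(starts[i])}|{strand}|{i}"
                reads.append((name, array_to_seq(mat[i])))
    return reads
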