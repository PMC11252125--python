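"""Preset scenarios emulating the study's locus architectures.

Two first-class presets exist:

* ``mv`` — a compact palindromic locus: two intact, inverted copies of the
  male-determining gene ~4.7 kb apart around a 3046 bp non-palindromic
  spacer, distal tandem-repeat blocks, terminal inverted repeats, a 9 bp
  target-site duplication (TTTTAGGTT) and ~31 kb total size.
* ``miii`` — a large tandem array: 88 head-to-tail gene copies, exactly one
  with an intact ORF (index 35), interleaved with non-gene repeats.

A third builder emulates the smaller of the two tandem-array contigs, where
truncated copies cover ~13% of a ~200 kb contig.

All sequences are generated deterministically from the given seed; the
structural constants above are the preset, the chromosome sizes are
desk-scale stand-ins for whole chromosomes.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .seqs import BASES, STOP_CODONS, random_orf, random_seq
from .synthio import (GenomeBlueprint, Individuals, PalindromeArchitecture,
                      TandemArrayArchitecture, TruthRecord,
                      build_palindromic_locus, build_tandem_array_locus,
                      make_individuals, shift_truth)

DEFAULT_TSD = "TTTTAGGTT"
GENE_CODONS = 733            # 2199 bp male-determining gene analog

#: per-copy unique divergent-site counts of the intact copies in the five
#: M-locus analogs (tandem-array III, II, Y, and the two palindrome copies)
DIVERGENCE_COUNTS = (("MIII", 8), ("MII", 4), ("MY", 6),
                     ("MV_A", 1), ("MV_B", 2))


def make_gene(seed: int = 42, n_codons: int = GENE_CODONS) -> str:
    return random_orf(np.random.default_rng(seed), n_codons)


def make_ref_genes(seed: int = 42) -> dict[str, str]:
    """Three single-copy autosomal reference gene analogs (transformer,
    yellow, asense roles)."""
    rng = np.random.default_rng(seed + 101)
    return {"tra": random_orf(rng, 501),
            "yel": random_orf(rng, 601),
            "ase": random_orf(rng, 401)}


def make_paralog(gene: str, divergence: float = 0.01, seed: int = 42) -> str:
    """A diverged paralog of the gene (off-target mapping source)."""
    rng = np.random.default_rng(seed + 202)
    arr = list(gene)
    n = max(1, int(round(divergence * len(gene))))
    for pos in rng.choice(len(gene), size=n, replace=False):
        pos = int(pos)
        arr[pos] = next(b for b in BASES if b != gene[pos])
    return "".join(arr)


def mv_architecture(gene: str | None = None, seed: int = 42,
                    total_len_target: int | None = 31000,
                    arm_substitutions: int = 1) -> PalindromeArchitecture:
    if gene is None:
        gene = make_gene(seed)
    rng = np.random.default_rng(seed + 303)
    return PalindromeArchitecture(
        gene_seq=gene,
        spacer_len=3046,
        intercopy_gap=4700,
        tsd_motif=DEFAULT_TSD,
        distal_repeat_unit=random_seq(rng, 171),
        distal_repeat_count=12,
        total_len_target=total_len_target,
        arm_substitutions=arm_substitutions,
    )


def miii_architecture(gene: str | None = None, seed: int = 42,
                      n_copies: int = 88, n_intact: int = 1,
                      truncation_min_frac: float = 0.15,
                      truncation_max_frac: float = 0.85,
                      intervening_frac: float = 0.45) -> TandemArrayArchitecture:
    if gene is None:
        gene = make_gene(seed)
    rng = np.random.default_rng(seed + 404)
    units = (random_seq(rng, 300), random_seq(rng, 500))
    intact = (35,) if n_intact == 1 and n_copies > 35 else None
    return TandemArrayArchitecture(
        gene_seq=gene, n_copies=n_copies, n_intact=n_intact,
        truncation_min_frac=truncation_min_frac,
        truncation_max_frac=truncation_max_frac,
        intervening_units=units, intervening_frac=intervening_frac,
        min_copy_len=300, intact_indices=intact, seed=seed + 1,
    )


@dataclass
class Scenario:
    """A fully generated study condition: architecture, locus, diploid
    individuals and merged ground truth."""
    name: str
    gene: str
    ref_genes: dict[str, str]
    locus: str
    locus_truth: TruthRecord
    blueprint: GenomeBlueprint
    individuals: Individuals
    truth: TruthRecord

    @property
    def m_contig(self) -> str:
        return self.individuals.male["M"][self.individuals.m_chrom]

    @property
    def non_m_contig(self) -> str:
        return self.individuals.male["A"][self.individuals.m_chrom]


def _build_scenario(name: str, gene: str, locus: str, locus_truth: TruthRecord,
                    seed: int, host_len: int, ref_chr_len: int,
                    paralog: tuple[str, str, int, str] | None = None) -> Scenario:
    ref_genes = make_ref_genes(seed)
    tra, yel, ase = (ref_genes[k] for k in ("tra", "yel", "ase"))
    blueprint = GenomeBlueprint(
        chromosomes=(("chrM", host_len), ("chrR1", ref_chr_len),
                     ("chrR2", ref_chr_len)),
        m_locus_placement=("chrM", host_len // 2),
        reference_genes=(("tra", "chrR1", 4000, tra),
                         ("yel", "chrR1", ref_chr_len // 2 + 2000, yel),
                         ("ase", "chrR2", 6000, ase)),
        tsd_motif=DEFAULT_TSD,
        paralog=paralog,
        seed=seed + 7,
    )
    inds = make_individuals(blueprint, locus)
    offset = inds.truth.data["locus_interval"][0]
    truth = TruthRecord({
        **inds.truth.data,
        "locus": shift_truth(locus_truth.data, offset),
        "gene_len": len(gene),
    })
    return Scenario(name, gene, ref_genes, locus, locus_truth, blueprint,
                    inds, truth)


def mv_scenario(seed: int = 42, host_len: int = 60000,
                ref_chr_len: int = 25000, with_paralog: bool = False) -> Scenario:
    gene = make_gene(seed)
    arch = mv_architecture(gene, seed)
    locus, locus_truth = build_palindromic_locus(arch, seed + 1)
    paralog = None
    if with_paralog:
        paralog = ("ncm", "chrR2", ref_chr_len - 4000, make_paralog(gene, seed=seed))
    return _build_scenario("mv", gene, locus, locus_truth, seed,
                           host_len, ref_chr_len, paralog)


def miii_scenario(seed: int = 42, host_len: int = 60000,
                  ref_chr_len: int = 25000, n_copies: int = 88,
                  n_intact: int = 1,
                  truncation_min_frac: float = 0.15,
                  truncation_max_frac: float = 0.85) -> Scenario:
    gene = make_gene(seed)
    arch = miii_architecture(gene, seed, n_copies=n_copies, n_intact=n_intact,
                             truncation_min_frac=truncation_min_frac,
                             truncation_max_frac=truncation_max_frac)
    locus, locus_truth = build_tandem_array_locus(arch)
    return _build_scenario("miii", gene, locus, locus_truth, seed,
                           host_len, ref_chr_len)


def contig1_scenario(seed: int = 42, truncated_target_frac: float = 0.13
                     ) -> tuple[str, TruthRecord, str]:
    """A tandem-array contig whose truncated-copy union covers a target
    fraction (default 13%) of a ~200 kb contig.

    The array (24 truncated copies + 1 intact) is generated first; the contig
    is then padded with random flanks so the truth union of truncated-copy
    intervals sits at the target fraction. Returns (contig, truth, gene).
    """
    gene = make_gene(seed)
    arch = miii_architecture(gene, seed, n_copies=25, n_intact=1,
                             truncation_min_frac=0.3, truncation_max_frac=0.7,
                             intervening_frac=0.35)
    arch = replace(arch, intact_indices=(12,))
    locus, locus_truth = build_tandem_array_locus(arch)
    trunc_total = sum(c["interval"][1] - c["interval"][0]
                      for c in locus_truth.data["copies"] if not c["intact"])
    contig_len = int(round(trunc_total / truncated_target_frac))
    rng = np.random.default_rng(seed + 505)
    left = (contig_len - len(locus)) // 2
    right = contig_len - len(locus) - left
    contig = random_seq(rng, left) + locus + random_seq(rng, right)
    truth = TruthRecord({
        **shift_truth(locus_truth.data, left),
        "contig_len": contig_len,
        "truncated_fraction": trunc_total / contig_len,
    })
    return contig, truth, gene


def divergence_copies(seed: int = 42) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Five intact-ORF copies of one base gene carrying disjoint unique
    substitution sets with the per-locus counts of :data:`DIVERGENCE_COUNTS`.

    Substitutions never touch the start/stop codons and never create a stop,
    so every copy remains a complete ORF. Returns (named copies, truth counts).
    """
    base = make_gene(seed)
    rng = np.random.default_rng(seed + 606)
    total = sum(n for _, n in DIVERGENCE_COUNTS)
    candidates = rng.permutation(np.arange(3, len(base) - 3))
    positions: list[int] = []
    copies: list[tuple[str, str]] = []
    chosen: list[tuple[int, str]] = []
    for pos in candidates:
        pos = int(pos)
        if len(chosen) == total:
            break
        ci = pos // 3
        codon = base[ci * 3:ci * 3 + 3]
        off = pos % 3
        alts = [b for b in BASES
                if b != base[pos]
                and codon[:off] + b + codon[off + 1:] not in STOP_CODONS]
        if not alts or ci in {p // 3 for p, _ in chosen}:
            continue
        chosen.append((pos, alts[int(rng.integers(0, len(alts)))]))
    if len(chosen) < total:
        raise RuntimeError("not enough substitution sites")
    cursor = 0
    for name, n in DIVERGENCE_COUNTS:
        arr = list(base)
        for pos, alt in chosen[cursor:cursor + n]:
            arr[pos] = alt
        cursor += n
        copies.append((name, "".join(arr)))
    return copies, dict(DIVERGENCE_COUNTS)
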