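"""Read placement, depth, copy-number normalisation, M-specific subtraction."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from protoy.covmap import (DepthTrack, Placement, classify_presence_patterns,
                           compute_depth, estimate_copy_number,
                           female_background_check, male_specific_intervals,
                           mask_female_covered, place_reads, read_depth_tsv,
                           write_depth_tsv)
from protoy.presets import mv_scenario
from protoy.seqs import random_seq, revcomp
from protoy.synthio import ReadSimParams, simulate_reads


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def test_unique_exact_read_gets_weight_one(rng):
    ref = random_seq(rng, 500)
    res = place_reads([("r1", ref[100:180])], {"ref": ref}, 2, 31)
    (p,) = res.placements
    assert (p.ref, p.start, p.strand, p.mismatches, p.weight) == ("ref", 100, "+", 0, 1.0)


def test_read_matching_two_identical_copies_splits_weight(rng):
    gene = random_seq(rng, 300)
    ref = gene + random_seq(rng, 200) + gene
    res = place_reads([("r1", gene[50:130])], {"ref": ref}, 2, 31)
    assert len(res.placements) == 2
    assert all(p.weight == 0.5 for p in res.placements)
    assert {p.start for p in res.placements} == {50, 550}


def test_reverse_strand_placement(rng):
    ref = random_seq(rng, 400)
    res = place_reads([("r1", revcomp(ref[40:140]))], {"ref": ref}, 2, 31)
    (p,) = res.placements
    assert (p.start, p.strand) == (40, "-")


def test_short_reads_are_skipped_and_counted(rng):
    ref = random_seq(rng, 200)
    res = place_reads([("tiny", "ACGTACGT")], {"ref": ref}, 2, 31)
    assert res.n_skipped == 1 and not res.placements


def _brute_force_place(read, refs, max_mismatches):
    """All equally-best substitution placements, by exhaustive scan."""
    hits = []
    for name, ref in refs.items():
        for oriented, strand in ((read, "+"), (revcomp(read), "-")):
            for start in range(len(ref) - len(read) + 1):
                mism = sum(a != b for a, b in
                           zip(ref[start:start + len(read)], oriented))
                if mism <= max_mismatches:
                    hits.append((name, start, strand, mism))
    if not hits:
        return []
    best = min(h[3] for h in hits)
    return sorted(h for h in hits if h[3] == best)


def test_placements_match_brute_force_scan(rng):
    ref = random_seq(rng, 2000)
    refs = {"ref": ref}
    reads = []
    for i in range(50):
        start = int(rng.integers(0, 2000 - 60))
        seq = ref[start:start + 60]
        if i % 3 == 0:
            seq = revcomp(seq)
        if i % 5 == 0:  # inject up to two substitutions
            arr = list(seq)
            for pos in rng.choice(60, size=int(rng.integers(1, 3)), replace=False):
                arr[pos] = next(b for b in "ACGT" if b != arr[pos])
            seq = "".join(arr)
        reads.append((f"r{i}", seq))
    # seed_len 20 keeps max_mismatches+1 seeds disjoint on 60 bp reads, so
    # the pigeonhole sensitivity guarantee holds and brute force must agree
    res = place_reads(reads, refs, max_mismatches=2, seed_len=20)
    by_read = {}
    for p in res.placements:
        by_read.setdefault(p.read, []).append((p.ref, p.start, p.strand, p.mismatches))
    for name, seq in reads:
        expected = _brute_force_place(seq, refs, 2)
        got = sorted(by_read.get(name, []))
        assert got == expected, name


# ---------------------------------------------------------------------------
# depth
# ---------------------------------------------------------------------------

def test_depth_of_no_placements_is_zero():
    track = compute_depth([], "ref", 50)
    assert not track.depth.any() and len(track) == 50


def test_depth_of_single_read():
    p = Placement("r", "ref", 10, 20, "+", 0, 1.0)
    track = compute_depth([p], "ref", 50)
    assert track.depth[9] == 0 and track.depth[10] == 1
    assert track.depth[29] == 1 and track.depth[30] == 0


def test_depth_conservation(rng):
    ref = random_seq(rng, 1500)
    reads = [(f"r{i}", ref[s:s + 70]) for i, s in
             enumerate(rng.integers(0, 1400, size=200))]
    res = place_reads(reads, {"ref": ref}, 2, 31)
    track = compute_depth(res, "ref", 1500)
    expected = sum(p.weight * p.length for p in res.placements)
    assert track.depth.sum() == pytest.approx(expected, rel=1e-9)


# ---------------------------------------------------------------------------
# depth TSV dialect
# ---------------------------------------------------------------------------

def test_depth_tsv_omits_zero_rows(tmp_path):
    track = DepthTrack("s", np.array([0.0, 2.0, 1.0]))
    path = tmp_path / "d.tsv"
    write_depth_tsv(track, path, omit_zeros=True)
    assert path.read_text() == "s\t2\t2\ns\t3\t1\n"


@given(st.lists(st.one_of(st.integers(0, 50),
                          st.floats(0, 50, allow_nan=False)),
                min_size=1, max_size=40))
def test_depth_tsv_round_trip(tmp_path_factory, depths):
    track = DepthTrack("chr", np.round(np.array(depths, dtype=float), 4))
    path = tmp_path_factory.mktemp("tsv") / "d.tsv"
    write_depth_tsv(track, path, omit_zeros=True)
    back = read_depth_tsv(path, length=len(track))
    assert np.allclose(back.depth, track.depth, atol=0)
    # integer depths are preserved exactly as integers in the file
    for line in path.read_text().splitlines():
        val = line.split("\t")[2]
        if float(val).is_integer():
            assert "." not in val


def test_depth_tsv_malformed_line_reports_line_number(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("s\t1\t4\ns\toops\n")
    with pytest.raises(ValueError, match="line 2"):
        read_depth_tsv(path)


def test_depth_tsv_position_out_of_bounds(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("s\t7\t4\n")
    with pytest.raises(ValueError, match="out of bounds"):
        read_depth_tsv(path, length=5)


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------

def _track(name, mean, n=100):
    return DepthTrack(name, np.full(n, float(mean)))


def test_diploid_single_copy_gene_estimates_two():
    est = estimate_copy_number(_track("t", 30), [_track("a", 30),
                                                 _track("b", 30),
                                                 _track("c", 30)])
    assert est.ratios == {"a": 1.0, "b": 1.0, "c": 1.0}
    assert est.copy_number == 2.0


def test_hemizygous_single_copy_estimates_one():
    est = estimate_copy_number(_track("t", 15), [_track("a", 30),
                                                 _track("b", 30),
                                                 _track("c", 30)])
    assert est.copy_number == 1.0


def test_copy_number_is_twice_mean_ratio_to_machine_precision(rng):
    t = DepthTrack("t", rng.uniform(1, 40, size=200))
    refs = [DepthTrack(n, rng.uniform(1, 40, size=150)) for n in "abc"]
    est = estimate_copy_number(t, refs)
    assert est.copy_number == 2.0 * np.mean(list(est.ratios.values()))


def test_zero_mean_reference_rejected():
    with pytest.raises(ValueError, match="zero mean"):
        estimate_copy_number(_track("t", 10), [_track("a", 0),
                                               _track("b", 30),
                                               _track("c", 30)])


def test_background_verdict_strict_at_threshold():
    # female mean exactly at the threshold fraction -> not negligible
    check = female_background_check(_track("t", 1.0), _track("t", 20.0), 0.05)
    assert check.female_mean == pytest.approx(1.0)
    assert not check.negligible
    check = female_background_check(_track("t", 0.0), _track("t", 20.0))
    assert check.negligible


def test_planted_paralog_produces_nonzero_female_background():
    sc = mv_scenario(23, host_len=20000, ref_chr_len=16000, with_paralog=True)
    reads = simulate_reads(sc.individuals.female,
                           ReadSimParams(100, 10.0, 0.0, 77), prefix="f")
    res = place_reads(reads, {"mdg": sc.gene}, max_mismatches=2, seed_len=31)
    track = compute_depth(res, "mdg", len(sc.gene))
    assert track.mean() > 0  # off-target mapping to the diverged paralog


# ---------------------------------------------------------------------------
# masking and male-specific intervals
# ---------------------------------------------------------------------------

def test_mask_examples():
    assert len(mask_female_covered(DepthTrack("s", np.zeros(50)), 1)) == 0
    mask = mask_female_covered(DepthTrack("s", np.full(50, 10.0)), 1)
    assert len(mask) == 50


def test_mask_size_matches_linear_scan(rng):
    depth = rng.poisson(2.0, size=500).astype(float)
    thr = 3
    mask = mask_female_covered(DepthTrack("s", depth), thr)
    assert len(mask) == sum(1 for v in depth if v >= thr)


def test_male_specific_simple_interval():
    male = DepthTrack("s", np.r_[np.zeros(100), np.full(100, 10.0), np.zeros(50)])
    res = male_specific_intervals(male, np.empty(0, dtype=int), min_cov=5)
    assert res.intervals == [(100, 200)]


def test_female_covering_everything_empties_result():
    male = DepthTrack("s", np.full(100, 10.0))
    res = male_specific_intervals(male, np.arange(100), min_cov=5)
    assert res.intervals == []


def test_intervals_never_overlap_mask_even_with_merge_gap(rng):
    male = DepthTrack("s", rng.poisson(8.0, size=300).astype(float))
    mask = np.flatnonzero(rng.random(300) < 0.1)
    res = male_specific_intervals(male, mask, min_cov=5, merge_gap=10)
    masked = set(mask.tolist())
    for s, e in res.intervals:
        assert not masked.intersection(range(s, e))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_monotonicity_in_min_cov_and_mask_threshold(seed):
    rng = np.random.default_rng(seed)
    male = DepthTrack("s", rng.poisson(6.0, size=400).astype(float))
    female = DepthTrack("s", rng.poisson(1.0, size=400).astype(float))

    def covered(min_cov, mask_thr):
        mask = mask_female_covered(female, mask_thr)
        res = male_specific_intervals(male, mask, min_cov=min_cov)
        out = set()
        for s, e in res.intervals:
            out.update(range(s, e))
        return out

    base = covered(5, 1)
    assert covered(8, 1) <= base          # raising min_cov never enlarges
    assert base <= covered(5, 2)          # raising mask threshold never shrinks


def test_bed_intervals_sorted_disjoint_within_bounds(rng):
    male = DepthTrack("s", rng.poisson(6.0, size=400).astype(float))
    res = male_specific_intervals(male, np.empty(0, dtype=int), min_cov=5)
    prev_end = 0
    for s, e in res.intervals:
        assert 0 <= s < e <= 400
        assert s >= prev_end
        prev_end = e


# ---------------------------------------------------------------------------
# presence patterns
# ---------------------------------------------------------------------------

def test_single_dataset_rejected_and_pair_partition():
    with pytest.raises(ValueError):
        classify_presence_patterns({"d1": [(0, 100)]})
    pat = classify_presence_patterns({"d1": [(0, 100)], "d2": [(50, 150)]})
    assert [(s.start, s.end, set(s.labels)) for s in pat.sections] == [
        (0, 50, {"d1"}), (50, 100, {"d1", "d2"}), (100, 150, {"d2"})]


def test_nested_subsets_recover_construction():
    sets = {
        "m3": [(0, 1000)],
        "lpr": [(0, 600)],
        "aabys": [(0, 400)],
        "m5": [(150, 300)],
        "m2": [(0, 200), (350, 500)],
    }
    pat = classify_presence_patterns(sets)
    # sections tile the covered region without overlap
    for a, b in zip(pat.sections[:-1], pat.sections[1:]):
        assert a.end <= b.start
    # every dataset's coverage is exactly reproduced by its labeled sections
    for name, ivs in sets.items():
        covered = sorted((s.start, s.end) for s in pat.sections
                         if name in s.labels)
        merged = []
        for s, e in covered:
            if merged and merged[-1][1] == s:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        assert merged == list(ivs)
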