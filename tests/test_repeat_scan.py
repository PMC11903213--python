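"""SSR, dispersed-repeat and tandem-array detection against brute-force oracles."""

import numpy as np
import pytest

from chondriome._seq import encode, random_dna, revcomp
from chondriome.repeat_scan import (
    SSRThresholds,
    find_dispersed_repeats,
    find_ssrs,
    find_tandem_repeats,
    repeat_summary,
)
from chondriome.synthetic_data import plant_repeats

THRESH = SSRThresholds.from_misa("1-10 2-5 3-4 4-3 5-3 6-3")


# ----------------------------------------------------------- SSR oracle

def _unit_periodic(unit):
    p = len(unit)
    return any(p % d == 0 and unit == unit[:d] * (p // d) for d in range(1, p))


def oracle_ssrs(seq, thresholds):
    """Position-by-position scan over every (start, unit size) pair."""
    out = []
    n = len(seq)
    for p in range(1, 7):
        i = 0
        while i + p <= n:
            if "N" in seq[i : i + p] or i + p >= n or seq[i] != seq[i + p]:
                i += 1
                continue
            j = i + p
            while j < n and seq[j] == seq[j - p] and seq[j] != "N":
                j += 1
            # the periodic region is [i, j); whole copies only
            copies = (j - i) // p
            unit = seq[i : i + p]
            if copies >= thresholds.minimum(p) and not _unit_periodic(unit):
                out.append((unit, p, copies, i + 1, i + copies * p))
            i = j - p + 1
    return sorted(out, key=lambda r: (r[3], r[1]))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_ssr_finder_matches_bruteforce_on_random_sequence(seed):
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, 20000, gc=0.4)
    # salt with plantable SSR arrays of several unit sizes
    seq, _ = plant_repeats(
        seq,
        ssr_spec=[("A", 12), ("AT", 7), ("ATC", 5), ("ATCG", 4), ("AACGT", 3), ("AACGTC", 3)],
        seed=seed,
    )
    got = [
        (r.motif, r.unit_size, r.copies, r.start, r.end) for r in find_ssrs(seq, THRESH)
    ]
    assert got == oracle_ssrs(seq, THRESH)


def test_monomer_at_exact_threshold_boundary():
    rng = np.random.default_rng(3)
    flank = random_dna(rng, 200).replace("A", "G")
    seq = flank + "A" * 10 + flank
    recs = find_ssrs(seq, THRESH)
    assert len(recs) == 1 and recs[0].motif == "A" and recs[0].copies == 10
    assert find_ssrs(flank + "A" * 9 + flank, THRESH) == []


def test_ssr_records_are_maximal_and_nonoverlapping():
    rng = np.random.default_rng(4)
    seq, _ = plant_repeats(random_dna(rng, 10000), ssr_spec=[("AT", 8), ("GTT", 6)], seed=4)
    recs = find_ssrs(seq, THRESH)
    by_motif = {}
    for r in recs:
        assert (r.end - r.start + 1) == r.unit_size * r.copies
        # extending by one unit in either direction must break the repeat
        left = seq[r.start - 1 - r.unit_size : r.start - 1]
        right = seq[r.end : r.end + r.unit_size]
        unit_at_start = seq[r.start - 1 : r.start - 1 + r.unit_size]
        assert left != unit_at_start
        assert right == "" or not (seq + "$" * 7)[r.end - r.unit_size: r.end] == right
        by_motif.setdefault(r.motif, []).append((r.start, r.end))
    for ivs in by_motif.values():
        ivs.sort()
        assert all(b0 > a1 for (_, a1), (b0, _) in zip(ivs, ivs[1:]))


def test_runs_of_n_break_the_scan():
    seq = "A" * 12 + "N" + "A" * 12
    recs = find_ssrs(seq, THRESH)
    assert [(r.start, r.end) for r in recs] == [(1, 12), (14, 25)]


def test_non_acgtn_characters_rejected():
    with pytest.raises(ValueError, match="non-ACGTN"):
        find_ssrs("ACGTX" * 10, THRESH)


def test_adjacent_ssrs_flagged_compound():
    rng = np.random.default_rng(5)
    left = random_dna(rng, 300).rstrip("A") + "C"
    right = "C" + random_dna(rng, 300)[1:]
    seq = left + "A" * 10 + "G" * 10 + right
    recs = {r.motif: r for r in find_ssrs(seq, THRESH)}
    assert recs["A"].compound and recs["G"].compound
    assert recs["A"].end + 1 == recs["G"].start


def test_circular_scan_finds_origin_crossing_ssr():
    rng = np.random.default_rng(6)
    body = random_dna(rng, 500).replace("A", "G")
    seq = "A" * 5 + body + "A" * 5  # a 10-copy monomer across the origin
    linear = find_ssrs(seq, THRESH)
    circular = find_ssrs(seq, THRESH, circular=True)
    assert linear == []
    assert any(r.motif == "A" and r.copies >= 10 for r in circular)


# ------------------------------------------------- dispersed repeats

def oracle_exact_pairs(seq, min_len):
    """All-shift equality scan: maximal same-strand and reverse-complement
    diagonal runs of length >= min_len."""
    enc = encode(seq)
    n = len(enc)
    pairs = set()

    def runs(eq):
        idx = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
        return zip(idx[::2], idx[1::2])

    for d in range(1, n - min_len + 1):
        eq = enc[: n - d] == enc[d:]
        for lo, hi in runs(eq):
            if hi - lo >= min_len:
                pairs.add(((int(lo), int(lo + hi - lo)), (int(lo + d), int(hi + d)), "forward"))
    rc = encode(revcomp(seq))
    for off in range(-(n - min_len), n - min_len + 1):
        a0, b0 = max(0, off), max(0, -off)
        m = n - abs(off)
        if m < min_len:
            continue
        eq = enc[a0 : a0 + m] == rc[b0 : b0 + m]
        for lo, hi in runs(eq):
            if hi - lo < min_len:
                continue
            ai, al = a0 + lo, hi - lo
            bj = b0 + lo
            bi = n - (bj + al)  # map reverse-complement coordinates back
            first, second = sorted([(int(ai), int(ai + al)), (int(bi), int(bi + al))])
            if first == second:
                continue
            pairs.add((first, second, "palindromic"))
    return pairs


@pytest.mark.parametrize("seed", [0, 1])
def test_exact_dispersed_pairs_match_all_shift_oracle(seed):
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, 8000)
    seq, _ = plant_repeats(
        seq, dispersed_spec=[(300, "forward"), (200, "palindromic"), (80, "forward")], seed=seed
    )
    got = {
        ((p.start_a - 1, p.end_a), (p.start_b - 1, p.end_b), p.orientation)
        for p in find_dispersed_repeats({"chr": seq}, min_len=30, min_identity=100.0)
    }
    assert got == oracle_exact_pairs(seq, 30)


def test_planted_forward_pair_detected_at_default_identity():
    rng = np.random.default_rng(7)
    seq, truth = plant_repeats(random_dna(rng, 6000), dispersed_spec=[(300, "forward")], seed=7)
    pairs = find_dispersed_repeats({"c": seq}, min_len=30, min_identity=90.0)
    fw = [p for p in pairs if p.orientation == "forward" and p.length >= 300]
    assert len(fw) == 1


def test_planted_palindromic_pair_detected():
    rng = np.random.default_rng(8)
    seq, truth = plant_repeats(random_dna(rng, 6000), dispersed_spec=[(300, "palindromic")], seed=8)
    pairs = find_dispersed_repeats({"c": seq}, min_len=30, min_identity=90.0)
    pal = [p for p in pairs if p.orientation == "palindromic" and p.length >= 300]
    assert len(pal) == 1


def test_orientation_classes_survive_whole_input_reverse_complement():
    rng = np.random.default_rng(9)
    seq, _ = plant_repeats(
        random_dna(rng, 6000), dispersed_spec=[(250, "forward"), (250, "palindromic")], seed=9
    )
    fwd = find_dispersed_repeats({"c": seq}, min_len=30, min_identity=100.0)
    rev = find_dispersed_repeats({"c": revcomp(seq)}, min_len=30, min_identity=100.0)
    count = lambda ps, o: sum(p.orientation == o for p in ps)
    assert count(fwd, "forward") == count(rev, "forward")
    assert count(fwd, "palindromic") == count(rev, "palindromic")


def test_dispersed_pairs_between_sequences_and_bounds():
    rng = np.random.default_rng(10)
    a = random_dna(rng, 3000)
    shared = a[1000:1400]
    b = random_dna(rng, 1500) + shared + random_dna(rng, 1500)
    pairs = find_dispersed_repeats({"a": a, "b": b}, min_len=50, min_identity=100.0)
    cross = [p for p in pairs if {p.id_a, p.id_b} == {"a", "b"}]
    assert any(p.length >= 400 for p in cross)
    for p in pairs:
        assert 1 <= p.start_a <= p.end_a
        assert 1 <= p.start_b <= p.end_b


def test_min_len_below_seed_size_rejected():
    with pytest.raises(ValueError, match="min_len"):
        find_dispersed_repeats({"c": "ACGT" * 100}, min_len=4)


# -------------------------------------------------------- tandem arrays

def test_perfect_tandem_array_is_called_exactly():
    rng = np.random.default_rng(11)
    flank = random_dna(rng, 1000)
    # boundary bases chosen so the array is maximal exactly as planted
    seq = flank[:-1] + "C" + "ACGTA" * 12 + "G" + flank[1:]
    recs = find_tandem_repeats(seq, min_period=2, max_period=100)
    hit = [r for r in recs if r.start <= 1001 <= r.end]
    assert len(hit) == 1
    assert hit[0].period == 5 and hit[0].copies == 12.0 and hit[0].percent_matches == 100.0


def test_substituted_base_lowers_percent_matches():
    rng = np.random.default_rng(12)
    flank = random_dna(rng, 1000)
    arr = list("ACGTA" * 12)
    arr[27] = "G" if arr[27] != "G" else "C"
    seq = flank + "".join(arr) + flank
    recs = find_tandem_repeats(seq, min_period=2, max_period=100)
    hit = [r for r in recs if r.start <= 1001 <= r.end and r.period == 5]
    assert hit and hit[0].percent_matches < 100.0


@pytest.mark.parametrize("seed", [0, 1])
def test_reported_arrays_verified_by_direct_realignment(seed):
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, 15000)
    seq = seq[:4000] + "TTAGGCA" * 9 + seq[4000:8000] + "ACCGTAGGATCC" * 6 + seq[8000:]
    enc = encode(seq)
    for r in find_tandem_repeats(seq, min_period=2, max_period=500, min_copies=2):
        span = r.end - r.start + 1
        assert span >= 2 * r.period  # at least two copies by construction
        a, b = r.start - 1, r.end - r.period
        agree = int(np.count_nonzero(enc[a:b] == enc[a + r.period : b + r.period]))
        pct = agree / (b - a) * 100.0
        assert pct == pytest.approx(r.percent_matches, abs=0.11)


# ----------------------------------------------------------- summaries

def test_empty_record_set_gives_all_zero_summary():
    df = repeat_summary(["chr1", "chr2"], [], [], [])
    assert (df.drop(columns="chromosome").to_numpy() == 0).all()


def test_planted_dimer_count_appears_in_summary():
    rng = np.random.default_rng(13)
    seq, _ = plant_repeats(
        random_dna(rng, 20000), ssr_spec=[("AT", 6), ("CA", 7), ("GT", 6), ("TC", 8), ("AG", 6)],
        seed=13,
    )
    recs = find_ssrs(seq, THRESH, chromosome="chr1")
    df = repeat_summary(["chr1"], recs)
    assert df.loc[0, "dimer"] >= 5
    assert set(df.columns) == {
        "chromosome", "monomer", "dimer", "trimer", "tetramer", "pentamer", "hexamer",
        "tandem", "forward", "palindromic",
    }


def test_summary_rejects_unknown_chromosome():
    rng = np.random.default_rng(14)
    recs = find_ssrs("A" * 15, THRESH, chromosome="chrX")
    with pytest.raises(ValueError, match="chrX"):
        repeat_summary(["chr1"], recs)
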