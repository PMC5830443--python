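"""Interval engine and flat-file round trips, checked against brute force."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sweepscape.genome_io import (
    FeatureSet,
    GenomeLayout,
    GenomicInterval,
    any_overlap,
    closest,
    intersect,
    read_bed,
    read_chain,
    read_genotype_matrix,
    read_layout,
    read_vcf,
    shuffle,
    write_bed,
    write_chain,
    write_genotype_matrix,
    write_layout,
    write_vcf,
)

from conftest import make_table, random_feature_set


# ---------------------------------------------------------------- containers


def test_layout_invariants():
    with pytest.raises(ValueError):
        GenomeLayout(("chr1", "chr1"), (10, 20))
    with pytest.raises(ValueError):
        GenomeLayout(("chr1",), (0,))
    lay = GenomeLayout(("chr1", "chr2"), (100, 200))
    assert lay.total_length == 300
    assert lay.length_of("chr2") == 200


def test_interval_validation():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 10, 10)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -1, 5)
    assert len(GenomicInterval("chr1", 3, 10)) == 7


def test_featureset_merged_union():
    fs = FeatureSet(
        "x",
        [
            GenomicInterval("chr1", 0, 10),
            GenomicInterval("chr1", 5, 20),
            GenomicInterval("chr1", 30, 40),
        ],
    )
    m = fs.merged()
    assert [(iv.start, iv.end) for iv in m] == [(0, 20), (30, 40)]
    assert m.total_length == 30


# ------------------------------------------------------------------ BED I/O


def test_bed_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    lay = GenomeLayout(("chr1", "chr2"), (1_000_000, 500_000))
    fs = random_feature_set(rng, lay, 1000)
    p = tmp_path / "x.bed"
    write_bed(fs, p)
    back = read_bed(p, "x")
    assert [(iv.chrom, iv.start, iv.end) for iv in back] == [
        (iv.chrom, iv.start, iv.end) for iv in fs
    ]


def test_bed_single_interval(tmp_path):
    p = tmp_path / "one.bed"
    p.write_text("chr1\t100\t200\n")
    fs = read_bed(p, "one")
    assert len(fs) == 1 and fs[0].start == 100 and fs[0].end == 200


@pytest.mark.parametrize("line", ["chr1\t-5\t100\n", "chr1\t200\t100\n"])
def test_bed_invalid_coordinates_name_line(tmp_path, line):
    p = tmp_path / "bad.bed"
    p.write_text("chr1\t1\t2\n" + line)
    with pytest.raises(ValueError, match=":2"):
        read_bed(p)


def test_layout_round_trip(tmp_path):
    lay = GenomeLayout(("chrA", "chrB"), (123, 456))
    p = tmp_path / "layout.tsv"
    write_layout(lay, p)
    assert read_layout(p) == lay


# ---------------------------------------------------------------- chain I/O


def test_chain_identity_round_trip(tmp_path):
    from sweepscape.genome_io import AlignmentChain, ChainSet

    chain = AlignmentChain(
        score=10_000, t_name="chr1", t_size=10_000, t_start=0, t_end=10_000,
        q_name="c1", q_size=10_000, q_strand="+", q_start=0, q_end=10_000,
        chain_id=1, blocks=np.array([[10_000, 0, 0]]),
    )
    cs = ChainSet([chain])
    p = tmp_path / "id.chain"
    write_chain(cs, p)
    back = read_chain(p)
    assert len(back) == 1
    assert back.chains[0].blocks.shape == (1, 3)
    assert back.chains[0].t_end == 10_000


def test_chain_with_gap_preserved(tmp_path):
    p = tmp_path / "gap.chain"
    p.write_text(
        "chain 900 chr1 1000 + 0 1000 c1 1100 + 0 1100 5\n"
        "500\t0\t100\n500\n\n"
    )
    cs = read_chain(p)
    c = cs.chains[0]
    assert c.chain_id == 5
    assert list(c.blocks[0]) == [500, 0, 100]


def test_chain_truncated_is_error(tmp_path):
    p = tmp_path / "trunc.chain"
    p.write_text("chain 900 chr1 1000 + 0 1000 c1 1100 + 0 1100 5\n500\t0\t100\n")
    with pytest.raises(ValueError, match="truncated"):
        read_chain(p)


def test_chain_inconsistent_blocks_error(tmp_path):
    p = tmp_path / "bad.chain"
    p.write_text("chain 900 chr1 1000 + 0 1000 c1 1100 + 0 1100 7\n400\t0\t100\n500\n\n")
    with pytest.raises(ValueError, match="7"):
        read_chain(p)


# ----------------------------------------------------------------- VCF I/O


def test_vcf_round_trip_and_flags(tmp_path):
    t = make_table([[0, 1], [2, -1], [1, 1]], [[0, 0], [1, 2], [2, 0]])
    t.sites.loc[1, "multiallelic"] = True
    p = tmp_path / "x.vcf"
    write_vcf(t, p)
    pm = {s: ("domestic" if s.startswith("d") else "wild") for s in t.samples}
    back = read_vcf(p, pm)
    assert back.n_sites == 3
    assert back.gt.shape == (3, 4)
    np.testing.assert_array_equal(back.gt, t.gt)
    assert bool(back.sites.loc[1, "multiallelic"])
    assert list(back.sites["pos"]) == list(t.sites["pos"])


def test_vcf_sample_missing_from_map(tmp_path):
    t = make_table([[0, 1]], [[1, 0]])
    p = tmp_path / "x.vcf"
    write_vcf(t, p)
    with pytest.raises(ValueError, match="absent"):
        read_vcf(p, {"d0": "domestic"})


def test_genotype_matrix_round_trip(tmp_path):
    t = make_table([[0, 1], [2, -1]], [[0, 2], [1, 1]])
    p = tmp_path / "gm.tsv"
    write_genotype_matrix(t, p)
    pm = {s: ("domestic" if s.startswith("d") else "wild") for s in t.samples}
    back = read_genotype_matrix(p, pm)
    np.testing.assert_array_equal(back.gt, t.gt)
    assert list(back.sites["pos"]) == list(t.sites["pos"])


# ------------------------------------------------------ intersect / closest


def _brute_overlaps(a, b):
    out = []
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            if x.overlaps(y):
                out.append((i, j, min(x.end, y.end) - max(x.start, y.start)))
    return sorted(out)


def test_intersect_simple():
    a = FeatureSet("a", [GenomicInterval("chr1", 0, 10)])
    b = FeatureSet("b", [GenomicInterval("chr1", 5, 15)])
    df = intersect(a, b)
    assert len(df) == 1 and df.loc[0, "overlap_bp"] == 5


def test_intersect_disjoint_zero():
    a = FeatureSet("a", [GenomicInterval("chr1", 0, 10)])
    b = FeatureSet("b", [GenomicInterval("chr1", 20, 30)])
    assert len(intersect(a, b)) == 0
    assert any_overlap(a, b) == 0


def test_intersect_namespace_mismatch():
    a = FeatureSet("a", [GenomicInterval("chr1", 0, 10)])
    b = FeatureSet("b", [GenomicInterval("1", 0, 10)])
    with pytest.raises(ValueError, match="chromosome"):
        intersect(a, b)


@pytest.mark.parametrize("seed", range(5))
def test_intersect_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    lay = GenomeLayout(("chr1", "chr2"), (5_000, 3_000))
    a = random_feature_set(rng, lay, 200, name="a")
    b = random_feature_set(rng, lay, 200, name="b")
    df = intersect(a, b)
    got = sorted(zip(df["a_index"], df["b_index"], df["overlap_bp"]))
    assert got == _brute_overlaps(a, b)
    hits = {i for i, _, _ in got}
    assert any_overlap(a, b) == len(hits)


def _brute_closest(x, b):
    best = None
    for j, y in enumerate(b):
        if y.chrom != x.chrom:
            continue
        if x.overlaps(y):
            d = 0
        else:
            d = max(y.start - x.end, x.start - y.end)
        if best is None or (d, y.start) < best[:2]:
            best = (d, y.start, j)
    return best


def test_closest_simple_cases():
    genes = FeatureSet("g", [GenomicInterval("chr1", 1000, 2000, name="G1")])
    inside = FeatureSet("f", [GenomicInterval("chr1", 1500, 1600)])
    assert closest(inside, genes).loc[0, "abs_distance"] == 0
    after = FeatureSet("f", [GenomicInterval("chr1", 2500, 2600)])
    row = closest(after, genes).loc[0]
    assert row["abs_distance"] == 500 and row["distance"] == -500
    other = FeatureSet("f", [GenomicInterval("chr2", 0, 10)])
    assert np.isnan(closest(other, genes).loc[0, "distance"])


@pytest.mark.parametrize("seed", range(5))
def test_closest_matches_brute_force(seed):
    rng = np.random.default_rng(100 + seed)
    lay = GenomeLayout(("chr1", "chr2"), (5_000, 3_000))
    a = random_feature_set(rng, lay, 150, name="a")
    b = random_feature_set(rng, lay, 150, name="b")
    df = closest(a, b)
    for i, x in enumerate(a):
        want = _brute_closest(x, b)
        assert df.loc[i, "abs_distance"] == want[0]
        got_j = int(df.loc[i, "b_index"])
        # tie-break: same distance and same (minimal) start coordinate
        assert b[got_j].start == want[1]


# ------------------------------------------------------------------ shuffle


def test_shuffle_preserves_lengths_and_is_deterministic(tiny_layout):
    rng = np.random.default_rng(3)
    fs = random_feature_set(rng, tiny_layout, 50, max_len=300)
    s1 = shuffle(fs, tiny_layout, seed=42)
    s2 = shuffle(fs, tiny_layout, seed=42)
    assert sorted(len(iv) for iv in s1) == sorted(len(iv) for iv in fs)
    assert [(iv.chrom, iv.start) for iv in s1] == [(iv.chrom, iv.start) for iv in s2]
    # non-overlap among placed intervals
    m = s1.merged()
    assert m.total_length == s1.total_length


def test_shuffle_infeasible_packing_errors():
    lay = GenomeLayout(("chr1",), (100,))
    fs = FeatureSet("f", [GenomicInterval("chr1", 0, 60), GenomicInterval("chr1", 0, 60)])
    with pytest.raises((RuntimeError, ValueError)):
        shuffle(fs, lay, seed=0, max_tries=50)


@settings(max_examples=50, derandomize=True)
@given(
    ivs=st.lists(
        st.tuples(st.integers(0, 9_000), st.integers(1, 900)),
        min_size=1, max_size=30,
    )
)
def test_merged_equals_interval_union_oracle(ivs):
    """merged() covers exactly the set of covered bases (brute force)."""
    fs = FeatureSet(
        "x", [GenomicInterval("chr1", s, s + l) for s, l in ivs]
    )
    covered = set()
    for s, l in ivs:
        covered.update(range(s, s + l))
    m = fs.merged()
    got = set()
    for iv in m:
        assert iv.chrom == "chr1"
        got.update(range(iv.start, iv.end))
    assert got == covered
    # merged intervals are sorted and disjoint
    pairs = [(iv.start, iv.end) for iv in m]
    assert pairs == sorted(pairs)
    assert all(a[1] < b[0] for a, b in zip(pairs, pairs[1:]))


@settings(max_examples=30, derandomize=True)
@given(
    a=st.lists(st.tuples(st.integers(0, 3_000), st.integers(1, 400)),
               min_size=1, max_size=20),
    b=st.lists(st.tuples(st.integers(0, 3_000), st.integers(1, 400)),
               min_size=1, max_size=20),
)
def test_any_overlap_equals_brute_force(a, b):
    fa = FeatureSet("a", [GenomicInterval("chr1", s, s + l) for s, l in a])
    fb = FeatureSet("b", [GenomicInterval("chr1", s, s + l) for s, l in b])
    brute = sum(
        1 for x in fa if any(x.overlaps(y) for y in fb)
    )
    assert any_overlap(fa, fb) == brute


def test_shuffle_placement_uniform():
    """Start positions of a 10 bp interval on a 100 bp genome are uniform."""
    lay = GenomeLayout(("chr1",), (100,))
    fs = FeatureSet("f", [GenomicInterval("chr1", 0, 10)])
    counts = np.zeros(91, dtype=int)
    for seed in range(10_000):
        counts[shuffle(fs, lay, seed=seed)[0].start] += 1
    _, p = stats.chisquare(counts)
    assert p > 0.01
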