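"""FST against an independent variance-components oracle, window stats,
outlier calling, region merging and the population summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sweepscape.genome_io import FeatureSet, GenomeLayout, GenomicInterval
from sweepscape.sweep_scan import (
    af_correlation,
    assign_genes,
    call_outliers,
    feature_pi,
    merge_regions,
    shared_polymorphism_summary,
    site_fst,
    window_stats,
)

from conftest import make_table


# --------------------------------------------------------------- FST oracle


def wc_theta_oracle(counts1, counts2):
    """Two-population Weir-Cockerham theta from genotype count triples.

    Independent scalar evaluation of the 1984 variance components a, b, c
    from (n_hom_ref, n_het, n_hom_alt) per population; returns NaN when
    undefined.
    """
    r = 2
    ns, ps, hs = [], [], []
    for hom_ref, het, hom_alt in (counts1, counts2):
        n = hom_ref + het + hom_alt
        if n < 2:
            return float("nan")
        ns.append(n)
        ps.append((2 * hom_alt + het) / (2 * n))
        hs.append(het / n)
    n1, n2 = ns
    p1, p2 = ps
    h1, h2 = hs
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    if pbar <= 0 or pbar >= 1:
        return float("nan")
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    return float("nan") if denom == 0 else a / denom


def gt_from_counts(c):
    return [0] * c[0] + [1] * c[1] + [2] * c[2]


def test_theta_fixed_difference_is_one():
    v = make_table([[0] * 10], [[2] * 10])
    assert site_fst(v)[0] == pytest.approx(1.0, abs=1e-15)


def test_theta_identical_populations_nonpositive():
    """Both populations with identical genotype class counts give theta <= 0,
    equal to the closed form to 1e-12."""
    c = (3, 4, 3)
    v = make_table([gt_from_counts(c)], [gt_from_counts(c)])
    want = wc_theta_oracle(c, c)
    assert want <= 0
    assert site_fst(v)[0] == pytest.approx(want, abs=1e-12)


def test_theta_hand_case():
    """p1=0.75 (AA,AA,Aa,Aa) vs p2=0.25 (aa,aa,Aa,Aa): matches the
    hand-evaluated variance components."""
    v = make_table([[2, 2, 1, 1]], [[0, 0, 1, 1]])
    want = wc_theta_oracle((0, 2, 2), (2, 2, 0))
    assert want == pytest.approx(1 / 3, abs=1e-12)
    assert site_fst(v)[0] == pytest.approx(want, abs=1e-12)


def test_theta_matches_oracle_on_random_configurations():
    """1000 random small genotype configurations agree with the independent
    oracle to 1e-12."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        n1, n2 = rng.integers(2, 12, 2)
        c1 = tuple(rng.multinomial(n1, [1 / 3] * 3))
        c2 = tuple(rng.multinomial(n2, [1 / 3] * 3))
        v = make_table([gt_from_counts(c1)], [gt_from_counts(c2)])
        got = site_fst(v)[0]
        want = wc_theta_oracle(c1, c2)
        if np.isnan(want):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-12)


def test_theta_undefined_when_population_missing():
    v = make_table([[-1, -1, -1]], [[0, 1, 2]])
    assert np.isnan(site_fst(v)[0])


# ------------------------------------------------------------- window stats


def test_window_mask_and_mean():
    lay = GenomeLayout(("chr1",), (40_000,))
    n = 19
    v = make_table(
        np.tile([0, 1, 2, 1], (n, 1)),
        np.tile([1, 1, 0, 2], (n, 1)),
        positions=np.arange(n) * 500,
    )
    w = window_stats(v, lay, min_snp=20)
    assert bool(w.loc[0, "masked"])
    assert w.loc[0, "n_snp"] == 19
    assert np.isnan(w.loc[0, "mean_fst"])


def test_window_mean_fst_is_arithmetic_mean():
    lay = GenomeLayout(("chr1",), (20_000,))
    configs = [
        ([2] * 8 + [1] * 2, [0] * 8 + [1] * 2),   # strongly diverged
        ([1] * 10, [1] * 10),                     # all het both
        ([0] * 5 + [1] * 5, [2] * 5 + [1] * 5),
    ]
    v = make_table(
        [c[0] for c in configs],
        [c[1] for c in configs],
        positions=[100, 5000, 15000],
    )
    theta = site_fst(v)
    w = window_stats(v, lay, min_snp=1)
    assert w.loc[0, "mean_fst"] == pytest.approx(np.nanmean(theta), abs=1e-12)


def test_window_order_invariance(default_sim):
    cfg, v = default_sim
    sub = v.subset(np.arange(v.n_sites) < 5000)
    perm = np.random.default_rng(0).permutation(5000)
    shuffled = sub.subset(np.zeros(5000, bool) | True)
    shuffled.sites = sub.sites.iloc[perm].reset_index(drop=True)
    shuffled.gt = sub.gt[perm]
    w1 = window_stats(sub, cfg.layout)
    w2 = window_stats(shuffled, cfg.layout)
    pd.testing.assert_frame_equal(w1, w2)


# ----------------------------------------------------------- outlier calls


def test_z_cutoff_at_alpha_001():
    rng = np.random.default_rng(1)
    w = pd.DataFrame(
        dict(
            chrom="chr1",
            start=np.arange(100) * 10_000,
            end=np.arange(100) * 10_000 + 20_000,
            n_snp=50,
            mean_fst=rng.normal(0.05, 0.01, 100),
            pi_dom=0.001,
            pi_wild=0.001,
            ln_ratio=rng.normal(0, 0.2, 100),
            masked=False,
        )
    )
    _, th = call_outliers(w, alpha=0.001)
    assert th["z_cutoff"] == pytest.approx(3.090, abs=1e-3)


def test_constant_bins_error():
    w = pd.DataFrame(
        dict(
            chrom="chr1", start=[0, 10_000], end=[20_000, 30_000],
            n_snp=50, mean_fst=0.1, pi_dom=0.001, pi_wild=0.001,
            ln_ratio=0.5, masked=False,
        )
    )
    with pytest.raises(ValueError, match="variance"):
        call_outliers(w)


def test_outlier_invariant_under_affine_rescaling():
    rng = np.random.default_rng(5)
    base = pd.DataFrame(
        dict(
            chrom="chr1",
            start=np.arange(500) * 10_000,
            end=np.arange(500) * 10_000 + 20_000,
            n_snp=50,
            mean_fst=rng.normal(0.05, 0.02, 500),
            pi_dom=0.001, pi_wild=0.001,
            ln_ratio=rng.normal(0, 0.3, 500),
            masked=False,
        )
    )
    out1, _ = call_outliers(base, alpha=0.01)
    scaled = base.copy()
    scaled["mean_fst"] = 3.0 * scaled["mean_fst"] + 1.0
    scaled["ln_ratio"] = 0.5 * scaled["ln_ratio"] - 2.0
    out2, _ = call_outliers(scaled, alpha=0.01)
    assert (out1["outlier"] == out2["outlier"]).all()


# ------------------------------------------------------------ region merge


def _merge_oracle(bins, gap):
    """Transitive closure by pairwise 'within gap on same chrom'."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(bins)))
    for i, (c1, s1, e1) in enumerate(bins):
        for j, (c2, s2, e2) in enumerate(bins):
            if i < j and c1 == c2 and max(s1, s2) - min(e1, e2) <= gap:
                g.add_edge(i, j)
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(
        (bins[c[0]][0], min(bins[i][1] for i in c), max(bins[i][2] for i in c))
        for c in comps
    )


def test_merge_simple_cases():
    bins = pd.DataFrame(
        dict(chrom="chr1", start=[0, 80_000], end=[20_000, 100_000],
             z_fst=[4.0, 5.0])
    )
    assert len(merge_regions(bins, gap=50_000)) == 2
    bins2 = pd.DataFrame(
        dict(chrom="chr1", start=[0, 10_000], end=[20_000, 30_000],
             z_fst=[4.0, 5.0])
    )
    regs = merge_regions(bins2, gap=50_000)
    assert len(regs) == 1
    assert (regs[0].start, regs[0].end) == (0, 30_000)
    assert regs[0].peak_z_fst == 5.0


@pytest.mark.parametrize("seed", range(10))
def test_merge_matches_transitive_closure_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 40))
    starts = np.sort(rng.choice(200, n, replace=False)) * 10_000
    chroms = np.where(starts < 1_000_000, "chr1", "chr2")
    bins = pd.DataFrame(
        dict(chrom=chroms, start=starts, end=starts + 20_000, z_fst=1.0)
    )
    regs = merge_regions(bins, gap=50_000)
    got = sorted((r.chrom, r.start, r.end) for r in regs)
    want = _merge_oracle(list(zip(chroms, starts, starts + 20_000)), 50_000)
    assert got == want


def test_assign_genes_distance_and_ties():
    bins = pd.DataFrame(
        dict(chrom="chr1", start=[100_000], end=[120_000], z_fst=[4.0])
    )
    regs = merge_regions(bins)
    genes = FeatureSet(
        "gene",
        [
            GenomicInterval("chr1", 130_000, 140_000, "+", "far"),
            GenomicInterval("chr1", 125_000, 126_000, "+", "near"),
        ],
    )
    assign_genes(regs, genes)
    assert regs[0].gene == "near"
    assert regs[0].gene_distance == 5_000


# --------------------------------------------------- population summaries


def test_shared_polymorphism_hand_count():
    # 10 sites: 6 segregate in domestic, of which 4 also in wild
    gt_d = [
        [0, 1], [0, 1], [0, 1], [0, 1], [0, 1], [0, 1],
        [0, 0], [2, 2], [0, 0], [1, 1],
    ]
    gt_w = [
        [0, 1], [1, 2], [0, 2], [1, 1], [0, 0], [2, 2],
        [0, 1], [0, 1], [0, 0], [2, 2],
    ]
    v = make_table(gt_d, gt_w)
    s = shared_polymorphism_summary(v)
    assert s["n_domestic_segregating"] == 7  # six planned + the [1,1] site
    assert s["n_shared"] == 4
    assert s["pct_shared_of_domestic"] == (100 * 4) // 7


def test_af_correlation_extremes():
    rng = np.random.default_rng(0)
    # identical AF vectors -> r = 1
    gt = rng.integers(0, 3, (50, 8)).astype(np.int8)
    v = make_table(gt, gt.copy())
    r, _, _ = af_correlation(v)
    assert r == pytest.approx(1.0, abs=1e-12)
    # anti-correlated constructed pair -> r = -1
    gt_d = np.array([[0, 0, 0, 1], [0, 0, 1, 1], [0, 1, 1, 1]], dtype=np.int8)
    gt_w = np.array([[0, 1, 1, 1], [0, 0, 1, 1], [0, 0, 0, 1]], dtype=np.int8)
    v2 = make_table(gt_d, gt_w)
    r2, _, _ = af_correlation(v2)
    assert r2 == pytest.approx(-1.0, abs=1e-12)


# -------------------------------------------------------------- feature pi


def test_feature_pi_identity_and_partition(default_sim):
    cfg, v = default_sim
    whole = FeatureSet(
        "genome",
        [GenomicInterval(c, 0, l) for c, l in cfg.layout.items()],
    )
    res = feature_pi(v, whole)
    w = window_stats(v, cfg.layout, bin_size=cfg.layout.lengths[0],
                     step=cfg.layout.lengths[0], min_snp=1)
    genome_pi_dom = res.loc[0, "pi_dom"]
    # two disjoint halves average (length-weighted) to the genome value
    halves = {
        "h1": FeatureSet("h1", [GenomicInterval("chr1", 0, cfg.layout.lengths[0])]),
        "h2": FeatureSet("h2", [GenomicInterval("chr2", 0, cfg.layout.lengths[1])]),
    }
    res2 = feature_pi(v, halves)
    weighted = (
        res2["pi_dom"] * res2["length"]
    ).sum() / res2["length"].sum()
    assert weighted == pytest.approx(genome_pi_dom, rel=1e-9)


def test_feature_pi_planted_low_diversity_promoters(default_sim):
    """Sweep windows (thinned domestic polymorphism) show lower domestic pi
    than matched neutral windows."""
    cfg, v = default_sim
    sweeps = FeatureSet(
        "sweeps",
        [GenomicInterval(s.chrom, s.start, s.end) for s in cfg.sweeps],
    )
    neutral = FeatureSet(
        "neutral",
        [GenomicInterval(s.chrom, s.start + 1_000_000, s.end + 1_000_000)
         for s in cfg.sweeps],
    )
    res = feature_pi(v, {"sweeps": sweeps, "neutral": neutral})
    pi = dict(zip(res["feature"], res["pi_dom"]))
    assert pi["sweeps"] < 0.3 * pi["neutral"]
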