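"""Windowed two-population selection scan.

The scan follows the classic domestication-sweep recipe: per-site
Weir & Cockerham (1984) theta between the domestic and wild populations,
averaged in 20 kb bins sliding by 10 kb; per-bin nucleotide diversity (pi)
within each population; the log wild/domestic pi ratio as the direction
signal; genome-wide Z-transformation of both statistics; and joint outlier
calling at a configurable one-sided significance level. Flagged bins within
50 kb of each other are merged into sweep regions and annotated with the
closest gene.

Per-site theta is the two-population variance-components estimator
theta = a / (a + b + c) computed from observed allele frequencies, sample
sizes and observed heterozygosities; negative values are retained in bin
means, and sites monomorphic across both populations are excluded.

The default pi estimator is the unbiased expected heterozygosity
2 p (1 - p) * 2n / (2n - 1) summed over sites and divided by bin width;
a literal "heterozygous-genotype count per bp" mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import FeatureSet, GenomeLayout, GenomicInterval, VariantTable, closest

__all__ = [
    "site_fst",
    "pi_site_contributions",
    "window_stats",
    "call_outliers",
    "merge_regions",
    "assign_genes",
    "shared_polymorphism_summary",
    "af_correlation",
    "feature_pi",
    "SweepRegion",
]


def _pop_stats(gt: np.ndarray):
    """Per-site (n called, alt AF, observed het fraction) for one population."""
    called = gt >= 0
    n = called.sum(axis=1)
    alt = np.where(called, gt, 0).sum(axis=1)
    het = np.where(called, gt == 1, False).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)
        h = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    return n.astype(float), p, h


def site_fst(v: VariantTable) -> np.ndarray:
    """Per-site Weir & Cockerham theta for the domestic/wild pair.

    NaN where either population has fewer than 2 called genotypes or the
    site is monomorphic across both populations; values may be negative.
    """
    n1, p1, h1 = _pop_stats(v.gt[:, v.pop_mask("domestic")])
    n2, p2, h2 = _pop_stats(v.gt[:, v.pop_mask("wild")])
    valid = (n1 >= 2) & (n2 >= 2)

    nbar = (n1 + n2) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = 2.0 * nbar - (n1**2 + n2**2) / (2.0 * nbar)
        pbar = (n1 * p1 + n2 * p2) / (2.0 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (2.0 * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 / 2.0 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)
    theta[~valid] = np.nan
    theta[(pbar <= 0) | (pbar >= 1)] = np.nan  # monomorphic overall
    return theta


def pi_site_contributions(
    v: VariantTable, population: str, mode: str = "unbiased"
) -> np.ndarray:
    """Per-site contribution to nucleotide diversity for one population.

    ``unbiased``: 2 p (1-p) * 2n/(2n-1) from the sample allele frequency.
    ``het_count``: 1 if the population carries >= 1 heterozygous genotype.
    Sites with < 2 called genotypes contribute 0.
    """
    g = v.gt[:, v.pop_mask(population)]
    n, p, h = _pop_stats(g)
    if mode == "unbiased":
        with np.errstate(invalid="ignore"):
            contrib = 2.0 * p * (1.0 - p) * (2.0 * n) / np.maximum(2.0 * n - 1.0, 1.0)
        return np.where(n >= 2, np.nan_to_num(contrib), 0.0)
    if mode == "het_count":
        return np.where((n >= 2) & (h > 0), 1.0, 0.0)
    raise ValueError(f"unknown pi mode {mode!r}")


def _bin_grid(layout: GenomeLayout, bin_size: int, step: int):
    """Sliding-bin grid per chromosome; only bins fully inside are kept."""
    frames = []
    for chrom, clen in layout.items():
        if clen < bin_size:
            continue
        starts = np.arange(0, clen - bin_size + 1, step)
        frames.append(
            pd.DataFrame(dict(chrom=chrom, start=starts, end=starts + bin_size))
        )
    return pd.concat(frames, ignore_index=True)


def window_stats(
    v: VariantTable,
    layout: GenomeLayout,
    bin_size: int = 20_000,
    step: int = 10_000,
    min_snp: int = 20,
    pi_mode: str = "unbiased",
    fst_mode: str = "mean_of_ratios",
) -> pd.DataFrame:
    """Sliding-bin SNP count, mean FST, per-population pi and ln pi-ratio.

    Bins with fewer than ``min_snp`` SNPs keep their count but carry no
    statistics (masked). ``fst_mode`` 'mean_of_ratios' averages per-site
    theta; 'ratio_of_averages' sums the variance components before the
    final ratio.
    """
    if bin_size % step != 0:
        raise ValueError("bin size must be a multiple of the step")
    k = bin_size // step
    bins = _bin_grid(layout, bin_size, step)
    key = {(c, s): i for i, (c, s) in enumerate(zip(bins["chrom"], bins["start"]))}

    theta = site_fst(v)
    pi_d = pi_site_contributions(v, "domestic", pi_mode)
    pi_w = pi_site_contributions(v, "wild", pi_mode)

    nb = len(bins)
    n_snp = np.zeros(nb)
    th_sum = np.zeros(nb)
    th_cnt = np.zeros(nb)
    pid_sum = np.zeros(nb)
    piw_sum = np.zeros(nb)

    chrom_arr = v.sites["chrom"].to_numpy()
    pos_arr = v.sites["pos"].to_numpy()
    th_ok = np.isfinite(theta)
    for chrom in np.unique(chrom_arr):
        m = chrom_arr == chrom
        pos = pos_arr[m]
        for r in range(k):
            b = pos // step - r
            start = b * step
            ok = b >= 0
            ids = np.array(
                [key.get((chrom, int(s)), -1) for s in start[ok]], dtype=int
            )
            good = ids >= 0
            ids = ids[good]
            rows = np.nonzero(m)[0][ok][good]
            np.add.at(n_snp, ids, 1)
            tm = th_ok[rows]
            np.add.at(th_sum, ids[tm], theta[rows[tm]])
            np.add.at(th_cnt, ids[tm], 1)
            np.add.at(pid_sum, ids, pi_d[rows])
            np.add.at(piw_sum, ids, pi_w[rows])

    if fst_mode == "mean_of_ratios":
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_fst = np.where(th_cnt > 0, th_sum / np.maximum(th_cnt, 1), np.nan)
    elif fst_mode == "ratio_of_averages":
        mean_fst = _ratio_of_averages_fst(v, bins, key, step, k)
    else:
        raise ValueError(f"unknown fst mode {fst_mode!r}")

    pi_dom = pid_sum / bin_size
    pi_wild = piw_sum / bin_size
    with np.errstate(invalid="ignore", divide="ignore"):
        ln_ratio = np.where(
            (pi_dom > 0) & (pi_wild > 0), np.log(pi_wild / pi_dom), np.nan
        )

    out = bins.copy()
    out["n_snp"] = n_snp.astype(int)
    masked = out["n_snp"] < min_snp
    out["mean_fst"] = np.where(masked, np.nan, mean_fst)
    out["pi_dom"] = np.where(masked, np.nan, pi_dom)
    out["pi_wild"] = np.where(masked, np.nan, pi_wild)
    out["ln_ratio"] = np.where(masked, np.nan, ln_ratio)
    out["masked"] = masked
    return out


def _ratio_of_averages_fst(v, bins, key, step, k):
    # sum a and a+b+c per bin, final ratio per bin
    n1, p1, h1 = _pop_stats(v.gt[:, v.pop_mask("domestic")])
    n2, p2, h2 = _pop_stats(v.gt[:, v.pop_mask("wild")])
    nbar = (n1 + n2) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = 2.0 * nbar - (n1**2 + n2**2) / (2.0 * nbar)
        pbar = (n1 * p1 + n2 * p2) / (2.0 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (2.0 * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 / 2.0 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    ok = (n1 >= 2) & (n2 >= 2) & (pbar > 0) & (pbar < 1)
    a = np.where(ok, a, 0.0)
    abc = np.where(ok, a + np.where(ok, b, 0) + np.where(ok, c, 0), 0.0)
    nb = len(bins)
    a_sum = np.zeros(nb)
    abc_sum = np.zeros(nb)
    chrom_arr = v.sites["chrom"].to_numpy()
    pos_arr = v.sites["pos"].to_numpy()
    for chrom in np.unique(chrom_arr):
        m = chrom_arr == chrom
        pos = pos_arr[m]
        for r in range(k):
            bidx = pos // step - r
            ok2 = bidx >= 0
            ids = np.array(
                [key.get((chrom, int(s * step)), -1) for s in bidx[ok2]],
                dtype=int,
            )
            good = ids >= 0
            rows = np.nonzero(m)[0][ok2][good]
            np.add.at(a_sum, ids[good], a[rows])
            np.add.at(abc_sum, ids[good], abc[rows])
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(abc_sum != 0, a_sum / np.where(abc_sum != 0, abc_sum, 1), np.nan)


def call_outliers(w: pd.DataFrame, alpha: float = 0.001):
    """Joint Z outlier calling on mean FST and ln pi-ratio.

    A bin is a domestic-direction outlier when the Z-scores of *both*
    statistics exceed the upper one-sided normal quantile for ``alpha``;
    wild-direction outliers use the lower tail of the ln ratio
    symmetrically. Returns (annotated copy, thresholds dict); the
    thresholds are the raw statistic values corresponding to ``alpha``.
    """
    ok = np.isfinite(w["mean_fst"]) & np.isfinite(w["ln_ratio"])
    if ok.sum() < 2:
        raise ValueError("need >= 2 unmasked bins with defined statistics")
    f = w.loc[ok, "mean_fst"].to_numpy()
    r = w.loc[ok, "ln_ratio"].to_numpy()
    f_mu, f_sd = f.mean(), f.std(ddof=1)
    r_mu, r_sd = r.mean(), r.std(ddof=1)
    if f_sd == 0 or r_sd == 0:
        raise ValueError("zero variance in a scan statistic; need larger input")
    zc = float(stats.norm.ppf(1.0 - alpha))
    out = w.copy()
    out["z_fst"] = (out["mean_fst"] - f_mu) / f_sd
    out["z_ratio"] = (out["ln_ratio"] - r_mu) / r_sd
    dom = (out["z_fst"] > zc) & (out["z_ratio"] > zc)
    wild = (out["z_fst"] > zc) & (-out["z_ratio"] > zc)
    out["outlier"] = (dom | wild).fillna(False)
    out["direction"] = np.where(dom, "domestic", np.where(wild, "wild", ""))
    thresholds = dict(
        z_cutoff=zc,
        fst_threshold=f_mu + zc * f_sd,
        ln_ratio_threshold=r_mu + zc * r_sd,
        ln_ratio_threshold_wild=r_mu - zc * r_sd,
        alpha=alpha,
    )
    return out, thresholds


@dataclass
class SweepRegion:
    chrom: str
    start: int
    end: int
    n_bins: int
    member_index: list
    peak_z_fst: float
    gene: str = ""
    gene_distance: float = np.nan

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def size(self) -> int:
        return self.end - self.start


def merge_regions(flagged: pd.DataFrame, gap: int = 50_000) -> list:
    """Single-linkage merge of flagged bins within ``gap`` bp on a chromosome."""
    regions = []
    if not len(flagged):
        return regions
    f = flagged.sort_values(["chrom", "start"])
    cur = None
    for row in f.itertuples():
        if (
            cur is not None
            and row.chrom == cur["chrom"]
            and row.start - cur["end"] <= gap
        ):
            cur["end"] = max(cur["end"], row.end)
            cur["members"].append(row.Index)
            cur["peak"] = max(cur["peak"], getattr(row, "z_fst", np.nan))
        else:
            if cur is not None:
                regions.append(cur)
            cur = dict(
                chrom=row.chrom, start=row.start, end=row.end,
                members=[row.Index], peak=getattr(row, "z_fst", np.nan),
            )
    regions.append(cur)
    return [
        SweepRegion(
            chrom=r["chrom"], start=int(r["start"]), end=int(r["end"]),
            n_bins=len(r["members"]), member_index=r["members"],
            peak_z_fst=float(r["peak"]),
        )
        for r in regions
    ]


def assign_genes(regions: list, genes: FeatureSet) -> list:
    """Attach the closest gene (tie: smaller start) and distance to each region."""
    if not len(genes):
        raise ValueError("gene set is empty")
    fs = FeatureSet("regions", [r.interval for r in regions])
    res = closest(fs, genes)
    for r, row in zip(regions, res.itertuples()):
        r.gene = row.b_name
        r.gene_distance = row.abs_distance
    return regions


def shared_polymorphism_summary(v: VariantTable) -> dict:
    """Counts of sites segregating in both, one or neither population.

    Percentages are integer-truncated for display, matching the usual
    shared-of-domestic framing ("x% of domestic SNPs are also polymorphic
    in the wild population").
    """
    afd = v.allele_frequency("domestic")
    afw = v.allele_frequency("wild")
    seg_d = (afd > 0) & (afd < 1)
    seg_w = (afw > 0) & (afw < 1)
    shared = int((seg_d & seg_w).sum())
    n_dom = int(seg_d.sum())
    n_wild = int(seg_w.sum())
    return dict(
        n_shared=shared,
        n_domestic_segregating=n_dom,
        n_wild_segregating=n_wild,
        n_domestic_private=n_dom - shared,
        n_wild_private=n_wild - shared,
        n_neither=int((~seg_d & ~seg_w).sum()),
        pct_shared_of_domestic=(100 * shared) // n_dom if n_dom else 0,
        pct_shared_of_wild=(100 * shared) // n_wild if n_wild else 0,
    )


def af_correlation(v: VariantTable):
    """Pearson r of reference-allele frequencies over shared-segregating sites."""
    afd = v.allele_frequency("domestic")
    afw = v.allele_frequency("wild")
    m = (afd > 0) & (afd < 1) & (afw > 0) & (afw < 1)
    if m.sum() < 3:
        raise ValueError("need >= 3 shared segregating sites")
    x, y = 1.0 - afd[m], 1.0 - afw[m]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in allele frequencies")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(m.sum())


def feature_pi(v: VariantTable, features, pi_mode: str = "unbiased") -> pd.DataFrame:
    """Nucleotide diversity per feature class per population.

    The pi estimator is restricted to sites inside the (merged) feature
    intervals and normalised by the merged feature length.
    """
    if isinstance(features, FeatureSet):
        features = {features.name: features}
    pi_d = pi_site_contributions(v, "domestic", pi_mode)
    pi_w = pi_site_contributions(v, "wild", pi_mode)
    chrom_arr = v.sites["chrom"].to_numpy()
    pos_arr = v.sites["pos"].to_numpy()
    rows = []
    for name, fs in features.items():
        if not len(fs):
            rows.append((name, 0, np.nan, np.nan, 0))
            continue
        merged = fs.merged()
        hit = np.zeros(v.n_sites, dtype=bool)
        for chrom in merged.chroms():
            ivs = [iv for iv in merged if iv.chrom == chrom]
            starts = np.array([iv.start for iv in ivs])
            ends = np.array([iv.end for iv in ivs])
            m = chrom_arr == chrom
            p = pos_arr[m]
            j = np.searchsorted(starts, p, side="right") - 1
            inside = (j >= 0) & (p < ends[np.clip(j, 0, None)])
            hit[np.nonzero(m)[0][inside]] = True
        length = merged.total_length
        rows.append(
            (
                name,
                length,
                pi_d[hit].sum() / length,
                pi_w[hit].sum() / length,
                int(hit.sum()),
            )
        )
    return pd.DataFrame(
        rows, columns=["feature", "length", "pi_dom", "pi_wild", "n_snp"]
    )
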