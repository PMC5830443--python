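"""Post-calling SNP filter cascade with per-rule accounting.

Seven rules are applied in a fixed order, and every removed site is
attributed to the *first* rule that rejects it, so the per-rule removal
counts plus the survivors always partition the input:

1. ``depth``            read depth outside [min_depth, 2 x per-sample mean]
                        in more than half of the samples
2. ``map_base_quality`` mapping quality < 30 or base quality < 20
3. ``near_indel``       within 5 bp of an indel
4. ``close_pair``       of any SNP pair separated by < 4 bp, the
                        lower-quality member is dropped
5. ``multiallelic``     tri-allelic (and higher) records
6. ``call_rate``        genotypes called in < 90% of samples
7. ``hwe_excess_het``   one-sided exact Hardy-Weinberg test toward
                        heterozygote excess, pooled over populations,
                        p < 0.001

Depth bounds are evaluated per sample against that sample's own mean
depth; a site fails when more than 50% of samples fall outside the window.
The heterozygote-excess test is the exact conditional test on the observed
allele counts, summing the probabilities of heterozygote counts at least
as large as observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .genome_io import VariantTable

__all__ = ["QcParams", "QcReport", "apply_qc", "hwe_excess_p", "RULES"]

RULES = (
    "depth",
    "map_base_quality",
    "near_indel",
    "close_pair",
    "multiallelic",
    "call_rate",
    "hwe_excess_het",
)


@dataclass(frozen=True)
class QcParams:
    min_depth: int = 5
    max_depth_factor: float = 2.0  # x per-sample mean depth
    min_mq: float = 30.0
    min_bq: float = 20.0
    indel_radius: int = 5
    close_pair_radius: int = 4  # pairs separated by < this many bp
    max_missingness: float = 0.10
    hwe_p: float = 0.001
    depth_sample_fraction: float = 0.5  # site fails if > this fraction fails

    def __post_init__(self):
        if self.min_depth <= 0 or self.indel_radius < 0 or self.close_pair_radius < 0:
            raise ValueError("thresholds must be positive")


@dataclass
class QcReport:
    removed: dict = field(default_factory=dict)
    n_input: int = 0
    n_surviving: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input)]
        rows += [(r, self.removed.get(r, 0)) for r in RULES]
        rows.append(("surviving", self.n_surviving))
        return pd.DataFrame(rows, columns=["rule", "sites"])

    def check_partition(self) -> bool:
        return sum(self.removed.values()) + self.n_surviving == self.n_input


def hwe_excess_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact one-sided HWE p-value toward heterozygote excess.

    Conditions on the observed allele counts and sums the exact
    probabilities of all heterozygote counts >= the observed one.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    nm = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)  # minor alleles
    hets = np.arange(nm % 2, nm + 1, 2)
    n_hom_m = (nm - hets) // 2
    n_hom_M = n - hets - n_hom_m
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(n_hom_m + 1)
        - gammaln(n_hom_M + 1)
    )
    logp -= logsumexp(logp)
    return float(np.exp(logsumexp(logp[hets >= n_het])))


def _depth_fail(v: VariantTable, params: QcParams) -> np.ndarray:
    if v.depth is None:
        raise ValueError("rule 'depth' requires per-sample depth annotations")
    sample_mean = v.depth.mean(axis=0)
    hi = params.max_depth_factor * sample_mean
    bad = (v.depth < params.min_depth) | (v.depth > hi[None, :])
    return bad.mean(axis=1) > params.depth_sample_fraction


def _close_pair_fail(sites: pd.DataFrame, alive: np.ndarray, radius: int) -> np.ndarray:
    """Mark the lower-quality member of each surviving pair < radius apart."""
    fail = np.zeros(len(sites), dtype=bool)
    idx = np.nonzero(alive)[0]
    sub = sites.iloc[idx]
    order = np.lexsort((sub["pos"].to_numpy(), sub["chrom"].to_numpy()))
    oidx = idx[order]
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    qual = sites["qual"].to_numpy()
    prev = None  # index of the surviving left member of the running chain
    for j in oidx:
        if prev is not None and chrom[j] == chrom[prev] and pos[j] - pos[prev] < radius:
            if qual[j] < qual[prev]:
                fail[j] = True
                continue  # prev stays the anchor
            else:  # ties drop the later site's rival: keep current
                fail[prev] = True
        prev = j
    return fail


def apply_qc(v: VariantTable, params: QcParams = QcParams()):
    """Run the filter cascade; returns (filtered table, QcReport)."""
    n = v.n_sites
    sites = v.sites
    alive = np.ones(n, dtype=bool)
    removed = {}

    def take(rule: str, fail: np.ndarray):
        hit = alive & fail
        removed[rule] = int(hit.sum())
        alive[hit] = False

    # (i) depth window
    take("depth", _depth_fail(v, params))

    # (ii) mapping / base quality
    mq = sites["mq"].to_numpy(dtype=float)
    bq = sites["bq"].to_numpy(dtype=float)
    if np.isnan(mq).all() and np.isnan(bq).all():
        raise ValueError("rule 'map_base_quality' requires MQ/BQ annotations")
    with np.errstate(invalid="ignore"):
        take("map_base_quality", (mq < params.min_mq) | (bq < params.min_bq))

    # (iii) proximity to indels
    fail = np.zeros(n, dtype=bool)
    if v.indels:
        ind = pd.DataFrame(v.indels, columns=["chrom", "pos"])
        for chrom, grp in ind.groupby("chrom"):
            ipos = np.sort(grp["pos"].to_numpy())
            m = (sites["chrom"] == chrom).to_numpy()
            if not m.any():
                continue
            spos = sites.loc[m, "pos"].to_numpy()
            j = np.searchsorted(ipos, spos)
            near = np.zeros(len(spos), dtype=bool)
            left = j > 0
            near[left] |= spos[left] - ipos[j[left] - 1] <= params.indel_radius
            right = j < len(ipos)
            near[right] |= ipos[j[right]] - spos[right] <= params.indel_radius
            fail[np.nonzero(m)[0][near]] = True
    take("near_indel", fail)

    # (iv) close pairs: lower-quality member removed
    take("close_pair", _close_pair_fail(sites, alive, params.close_pair_radius))

    # (v) tri-allelic
    take("multiallelic", sites["multiallelic"].to_numpy(dtype=bool))

    # (vi) call rate
    miss = (v.gt < 0).mean(axis=1)
    take("call_rate", miss > params.max_missingness)

    # (vii) heterozygote excess (pooled exact test)
    fail = np.zeros(n, dtype=bool)
    for i in np.nonzero(alive)[0]:
        g = v.gt[i]
        g = g[g >= 0]
        p = hwe_excess_p(int((g == 0).sum()), int((g == 1).sum()),
                         int((g == 2).sum()))
        fail[i] = p < params.hwe_p
    take("hwe_excess_het", fail)

    report = QcReport(removed=removed, n_input=n, n_surviving=int(alive.sum()))
    out = v.subset(alive)
    if v.depth is not None:
        out.depth = v.depth[alive]
    return out, report
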