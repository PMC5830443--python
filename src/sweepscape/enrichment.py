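"""Validation and enrichment statistics for genomic feature sets.

Three complementary tests:

* ``recovery_rate`` — what fraction of predicted elements is recovered by
  an experimental set (>= 1 bp overlap), reported as an integer-truncated
  percent for display with the exact fraction retained;
* ``empirical_overlap_p`` — a shuffle null: the features are re-placed
  uniformly at random ``n`` times and the empirical p-value is the
  fraction of randomisations whose overlap with the observed set is at
  least as large as the real one, with the standard (k+1)/(n+1)
  correction;
* ``locus_overlap_enrichment`` — the locus-overlap contingency test: with
  a universe of genomic bins, a reference subset (e.g. sweep-outlier
  bins) and a query feature set, a universe bin is a "hit" when it
  overlaps >= 1 query interval and a one-sided Fisher exact test asks
  whether hits are over-represented among reference bins, with
  Benjamini-Hochberg correction across query sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import FeatureSet, GenomeLayout, intersect, overlaps_any, shuffle

__all__ = [
    "RecoveryResult",
    "recovery_rate",
    "OverlapNull",
    "empirical_overlap_p",
    "locus_overlap_enrichment",
    "benjamini_hochberg",
]


@dataclass
class RecoveryResult:
    n_query: int
    n_hit: int
    fraction: float
    percent: int  # integer-truncated display percent


def recovery_rate(query: FeatureSet, subject: FeatureSet) -> RecoveryResult:
    """Percent of query intervals overlapped by >= 1 subject interval."""
    if not len(query):
        raise ValueError("query set is empty")
    n_hit = int(overlaps_any(query, subject).sum())
    return RecoveryResult(
        n_query=len(query),
        n_hit=n_hit,
        fraction=n_hit / len(query),
        percent=(100 * n_hit) // len(query),
    )


@dataclass
class OverlapNull:
    p: float
    observed: float
    n_random: int
    null_mean: float
    null_sd: float
    n_ge: int


def _overlap_stat(a: FeatureSet, b: FeatureSet, mode: str) -> float:
    if mode == "intervals":
        return float(overlaps_any(a, b).sum())
    if mode == "bases":
        df = intersect(a, b)
        return float(df["overlap_bp"].sum()) if len(df) else 0.0
    raise ValueError(f"unknown overlap mode {mode!r}")


def empirical_overlap_p(
    feature: FeatureSet,
    observed: FeatureSet,
    layout: GenomeLayout,
    n: int = 1000,
    seed=0,
    mode: str = "intervals",
) -> OverlapNull:
    """Shuffle-null empirical p for the overlap of ``feature`` with ``observed``.

    ``mode`` 'intervals' counts feature intervals hitting the observed set;
    'bases' counts overlapping base pairs. p = (k + 1) / (n + 1) where k is
    the number of randomisations with overlap >= observed.
    """
    obs = _overlap_stat(feature, observed, mode)
    rng = np.random.default_rng(seed)
    null = np.empty(n)
    for i in range(n):
        shuf = shuffle(feature, layout, rng.integers(0, 2**31 - 1))
        null[i] = _overlap_stat(shuf, observed, mode)
    k = int((null >= obs).sum())
    return OverlapNull(
        p=(k + 1) / (n + 1),
        observed=obs,
        n_random=n,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n > 1 else 0.0,
        n_ge=k,
    )


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted q-values (monotone in p)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def locus_overlap_enrichment(
    querysets,
    reference: FeatureSet,
    universe: FeatureSet,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher-exact locus overlap of query feature sets within outlier bins.

    ``reference`` must be a subset of ``universe`` by interval identity
    (chrom, start, end). For every query set the 2x2 contingency is
    (reference & hit, reference & ~hit, other & hit, other & ~hit); the
    one-sided Fisher exact test asks for enrichment and BH FDR is applied
    across query sets. Degenerate tables (hits covering all or none of
    the universe) are flagged.
    """
    if isinstance(querysets, dict):
        items = list(querysets.items())
    else:
        items = [(q.name, q) for q in querysets]
    if not items:
        raise ValueError("no query sets supplied")
    uni_keys = {(iv.chrom, iv.start, iv.end) for iv in universe}
    ref_keys = {(iv.chrom, iv.start, iv.end) for iv in reference}
    if not ref_keys <= uni_keys:
        raise ValueError("reference bins are not a subset of the universe")
    is_ref = np.array(
        [(iv.chrom, iv.start, iv.end) in ref_keys for iv in universe]
    )
    rows = []
    for name, q in items:
        if not len(q):
            raise ValueError(f"query set {name!r} is empty")
        hit = overlaps_any(universe, q)
        a = int((is_ref & hit).sum())
        b = int((is_ref & ~hit).sum())
        c = int((~is_ref & hit).sum())
        d = int((~is_ref & ~hit).sum())
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        degenerate = (b + d == 0) or (a + c == 0)
        rows.append(
            dict(
                feature=name, a=a, b=b, c=c, d=d,
                odds_ratio=float(odds), p=float(p), degenerate=degenerate,
            )
        )
    out = pd.DataFrame(rows)
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    out["neg_log10_p"] = -np.log10(np.maximum(out["p"], 1e-300))
    out["significant"] = out["q"] < alpha
    return out.sort_values("p", ignore_index=True)
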