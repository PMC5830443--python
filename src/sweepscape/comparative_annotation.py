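"""Chain-based interval projection with a minMatch criterion.

This is the mechanism behind comparative (cross-species) annotation
transfer: an interval projects through a pairwise alignment chain iff at
least ``min_match`` of its bases lie in aligned blocks of a single
best-scoring chain, and the projected interval is the span of the
block-wise images on the target genome. Intervals whose bases are claimed
by more than one qualifying chain are reported as ``split`` and rejected
rather than stitched. The reciprocal filter keeps a projection only when
projecting it back with the reverse chains recovers the original interval
with sufficient overlap — the standard reciprocal-best criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import ChainSet, FeatureSet, GenomicInterval

__all__ = ["ProjectionResult", "project", "reciprocal_filter", "reciprocal_map"]

MAPPED = "mapped"
SPLIT = "split"
BELOW_MINMATCH = "below_minmatch"
UNMAPPED = "unmapped"


@dataclass
class ProjectionResult:
    source: GenomicInterval
    target: GenomicInterval | None
    fraction: float
    status: str
    chain_id: int | None = None

    @property
    def mapped(self) -> bool:
        return self.status == MAPPED


def _project_through(chain, iv: GenomicInterval):
    """(matched bases, projected interval or None) for one chain."""
    if chain.t_name != iv.chrom:
        return 0, None
    t_starts, q_starts, sizes = chain.block_coords()
    t_ends = t_starts + sizes
    lo = np.searchsorted(t_ends, iv.start, side="right")
    hi = np.searchsorted(t_starts, iv.end, side="left")
    if hi <= lo:
        return 0, None
    os_ = np.maximum(t_starts[lo:hi], iv.start)
    oe = np.minimum(t_ends[lo:hi], iv.end)
    matched = int((oe - os_).sum())
    if matched <= 0:
        return 0, None
    qs = q_starts[lo:hi] + (os_ - t_starts[lo:hi])
    qe = qs + (oe - os_)
    q_lo, q_hi = int(qs.min()), int(qe.max())
    if chain.q_strand == "-":
        q_lo, q_hi = chain.q_size - q_hi, chain.q_size - q_lo
    strand = iv.strand
    if chain.q_strand == "-" and strand in "+-":
        strand = "+" if strand == "-" else "-"
    return matched, GenomicInterval(chain.q_name, q_lo, q_hi, strand, iv.name)


def project(
    intervals, chains: ChainSet, min_match: float = 0.1
) -> list:
    """Project intervals through ``chains``; one ProjectionResult each.

    ``intervals`` may be a FeatureSet or any iterable of GenomicInterval.
    """
    if not (0 < min_match <= 1):
        raise ValueError("min_match must be in (0, 1]")
    by_chrom = {}
    for c in chains:
        by_chrom.setdefault(c.t_name, []).append(c)
    results = []
    for iv in intervals:
        cands = []
        for c in by_chrom.get(iv.chrom, ()):
            matched, target = _project_through(c, iv)
            if matched > 0:
                cands.append((matched, c.score, c, target))
        if not cands:
            results.append(ProjectionResult(iv, None, 0.0, UNMAPPED))
            continue
        cands.sort(key=lambda x: (-x[0], -x[1]))
        L = len(iv)
        qualifying = [x for x in cands if x[0] / L >= min_match]
        best = cands[0]
        frac = best[0] / L
        if len(qualifying) > 1:
            results.append(
                ProjectionResult(iv, None, frac, SPLIT, best[2].chain_id)
            )
        elif frac < min_match:
            results.append(
                ProjectionResult(iv, None, frac, BELOW_MINMATCH, best[2].chain_id)
            )
        else:
            results.append(
                ProjectionResult(iv, best[3], frac, MAPPED, best[2].chain_id)
            )
    return results


def reciprocal_filter(
    forward: list,
    backward: list,
    min_back_overlap: float = 0.5,
    name: str = "projected",
) -> tuple:
    """Keep forward projections whose back-projection recovers the source.

    ``backward[i]`` must be the projection of ``forward_mapped[i].target``
    through the reciprocal chains, where ``forward_mapped`` is the mapped
    subset of ``forward`` in order. A projection is retained iff its back
    image lands on the source chromosome and overlaps the source interval
    by at least ``min_back_overlap`` of the source length.

    Returns (FeatureSet of retained target intervals, list of retained
    forward results).
    """
    fwd_mapped = [r for r in forward if r.mapped]
    if len(fwd_mapped) != len(backward):
        raise ValueError(
            "backward results must correspond 1:1 to mapped forward results"
        )
    kept_ivs, kept_res = [], []
    for f, b in zip(fwd_mapped, backward):
        if not b.mapped or b.target.chrom != f.source.chrom:
            continue
        ov = min(b.target.end, f.source.end) - max(b.target.start, f.source.start)
        if ov >= min_back_overlap * len(f.source):
            kept_ivs.append(f.target)
            kept_res.append(f)
    return FeatureSet(name, kept_ivs), kept_res


def reciprocal_map(
    features: FeatureSet,
    forward_chains: ChainSet,
    backward_chains: ChainSet,
    min_match: float = 0.1,
    min_back_overlap: float = 0.5,
) -> tuple:
    """Convenience: project, back-project, reciprocal-filter.

    Returns (retained FeatureSet named after ``features``, forward results).
    """
    fwd = project(features, forward_chains, min_match)
    mapped = [r for r in fwd if r.mapped]
    bwd = project((r.target for r in mapped), backward_chains, min_match)
    kept, _ = reciprocal_filter(fwd, bwd, min_back_overlap, name=features.name)
    kept.source_tag = features.source_tag
    return kept, fwd
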