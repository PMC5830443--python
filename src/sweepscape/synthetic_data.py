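"""Synthetic two-population genome data with planted selection signals.

The generator emulates the statistical structure the downstream analysis
assumes, so the whole pipeline can be exercised end to end without any
external data:

* two diploid populations ("domestic", n=67; "wild", n=17) whose allele
  frequencies share an ancestral frequency and diverge by bounded drift
  noise, giving the high between-population AF correlation seen in closely
  related domestic/wild pairs;
* genome-wide nucleotide diversity tuned to pi = 0.0016 (domestic) and
  0.0020 (wild) per bp;
* selective sweeps planted by direct manipulation: inside each sweep
  window the domestic allele frequency is shifted toward fixation by
  ``delta`` and domestic polymorphism is thinned to a fraction ``f_pi``;
* gene models with promoter-proximal and distal regulatory features whose
  distance-to-TSS geometry is controlled;
* experimental-style peak sets recovering a configurable fraction of a
  predicted feature set;
* pairwise alignment chains (plus their reciprocal) between the analysis
  genome and a synthetic donor genome, for the projection stage.

Sites are placed by a Poisson process whose rate is calibrated against the
allele-frequency law so that the expected per-bp heterozygosity matches the
configured pi targets; a final per-population contraction/expansion of
allele frequencies around 0.5 matches the realized mean heterozygosity to
the target on the actually-drawn sites. Ancestral frequencies follow a
neutral-like density proportional to 1/p truncated to [1/(2n), 1-1/(2n)].

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genome_io import (
    AlignmentChain,
    ChainSet,
    FeatureSet,
    GenomeLayout,
    GenomicInterval,
    VariantTable,
)

__all__ = [
    "SweepSpec",
    "SimConfig",
    "default_config",
    "simulate_variants",
    "simulate_features",
    "simulate_peaks",
    "simulate_chain",
    "simulate_qc_showcase",
]


@dataclass(frozen=True)
class SweepSpec:
    """A planted selective sweep: where, and how strong.

    ``f_pi`` is the fraction of domestic polymorphism retained inside the
    window (small = hard sweep); ``delta`` is the allele-frequency shift
    applied to the domestic population toward the nearer fixed state.
    """

    chrom: str
    start: int
    end: int
    f_pi: float = 0.05
    delta: float = 0.8

    def __post_init__(self):
        if not (0 < self.f_pi <= 1):
            raise ValueError("f_pi must be in (0, 1]")
        if not (0 <= self.delta <= 1):
            raise ValueError("delta must be in [0, 1]")
        if self.start >= self.end:
            raise ValueError("empty sweep window")


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome."""

    layout: GenomeLayout
    n_domestic: int = 67
    n_wild: int = 17
    pi_domestic: float = 0.0016
    pi_wild: float = 0.0020
    drift_sd: float = 0.08
    sweeps: list = field(default_factory=list)
    n_genes: int = 120
    promoter_halfwidth: int = 500
    enhancer_offset: int = 40_000
    proximal_offset: int = 1_500
    distal_offset: int = 100_000
    indel_rate_per_bp: float = 5e-4
    mean_depth: float = 11.8
    consequence_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_domestic < 2 or self.n_wild < 2:
            raise ValueError("need at least 2 samples per population")
        for pi in (self.pi_domestic, self.pi_wild):
            if not (0 < pi < 0.01):
                raise ValueError("pi targets must lie in (0, 0.01)")
        ivs = sorted(
            (s.chrom, s.start, s.end) for s in self.sweeps
        )
        for (c1, s1, e1), (c2, s2, e2) in zip(ivs, ivs[1:]):
            if c1 == c2 and s2 < e1:
                raise ValueError("sweep windows overlap")
        for s in self.sweeps:
            if s.chrom not in self.layout:
                raise ValueError(f"sweep chrom {s.chrom!r} not in layout")
            if s.end > self.layout.length_of(s.chrom):
                raise ValueError("sweep window exceeds chromosome length")


def default_config(seed: int = 0) -> SimConfig:
    """The default study conditions: ~2,000 sliding bins, five hard sweeps."""
    layout = GenomeLayout(("chr1", "chr2"), (10_000_000, 10_000_000))
    sweeps = [
        SweepSpec("chr1", 1_500_000, 1_560_000),
        SweepSpec("chr1", 4_800_000, 4_860_000),
        SweepSpec("chr1", 8_200_000, 8_260_000),
        SweepSpec("chr2", 2_600_000, 2_660_000),
        SweepSpec("chr2", 7_100_000, 7_160_000),
    ]
    return SimConfig(layout=layout, sweeps=sweeps, seed=seed)


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

_CONSEQUENCES = np.array(
    ["intergenic", "intron", "synonymous", "missense", "splice"]
)
_CONSEQUENCE_P = np.array([0.60, 0.385, 0.0075, 0.0070, 0.0005])

_BASES = np.array(list("ACGT"))


def _ancestral_freq(rng, n_sites: int, n_samples: int) -> np.ndarray:
    """Draw from density ~ 1/p truncated to [1/(2n), 1 - 1/(2n)]."""
    a = 1.0 / (2 * n_samples)
    b = 1.0 - a
    u = rng.random(n_sites)
    return a * (b / a) ** u


def _het(p: np.ndarray) -> np.ndarray:
    return 2.0 * p * (1.0 - p)


def _match_heterozygosity(af: np.ndarray, target_mean_het: float) -> np.ndarray:
    """Rescale AFs around 0.5 (with clipping) to hit a mean heterozygosity.

    kappa > 1 pushes frequencies toward fixation (lower diversity, some
    sites fix outright, creating private polymorphism in the other
    population); kappa < 1 compresses toward 0.5.
    """

    def mean_het(kappa):
        h = np.clip(0.5 + kappa * (af - 0.5), 0.0, 1.0)
        return _het(h).mean()

    lo, hi = 0.05, 80.0
    if mean_het(1.0) == target_mean_het:
        return af
    f = lambda k: mean_het(k) - target_mean_het
    if f(lo) * f(hi) > 0:  # target unreachable; do the best monotone clip
        kappa = lo if abs(f(lo)) < abs(f(hi)) else hi
    else:
        kappa = brentq(f, lo, hi, xtol=1e-6)
    return np.clip(0.5 + kappa * (af - 0.5), 0.0, 1.0)


def simulate_variants(cfg: SimConfig) -> VariantTable:
    """Generate the two-population variant table under ``cfg``.

    Site density is Poisson with a rate calibrated so the expected per-bp
    heterozygosity of the wild population matches ``pi_wild``; the realized
    mean heterozygosity of each population is then matched to its target on
    the drawn sites (outside sweep windows). Genotypes are binomial draws
    from the population allele frequency.
    """
    rng = np.random.default_rng(cfg.seed)
    n_tot = cfg.n_domestic + cfg.n_wild
    L = cfg.layout.total_length

    # calibrate the Poisson rate with a dedicated draw of the AF pipeline
    calib = _ancestral_freq(rng, 100_000, n_tot)
    calib_w = np.clip(calib + rng.normal(0, cfg.drift_sd, calib.size), 0, 1)
    lam = cfg.pi_wild / _het(calib_w).mean()

    n_sites = int(rng.poisson(lam * L))
    offsets = np.sort(rng.choice(L, size=n_sites, replace=False))
    cum = np.cumsum([0] + list(cfg.layout.lengths))
    chrom_idx = np.searchsorted(cum, offsets, side="right") - 1
    pos = offsets - cum[chrom_idx]
    chroms = np.array(cfg.layout.names)[chrom_idx]

    p = _ancestral_freq(rng, n_sites, n_tot)
    af_w = np.clip(p + rng.normal(0, cfg.drift_sd, n_sites), 0, 1)
    af_d = np.clip(p + rng.normal(0, cfg.drift_sd, n_sites), 0, 1)

    in_sweep = np.zeros(n_sites, dtype=bool)
    for s in cfg.sweeps:
        in_sweep |= (chroms == s.chrom) & (pos >= s.start) & (pos < s.end)

    # match realized mean heterozygosity to the pi targets on neutral sites
    neutral = ~in_sweep
    mean_het_w = cfg.pi_wild * L / max(n_sites, 1)
    mean_het_d = cfg.pi_domestic * L / max(n_sites, 1)
    af_w[neutral] = _match_heterozygosity(af_w[neutral], mean_het_w)
    af_d[neutral] = _match_heterozygosity(af_d[neutral], mean_het_d)

    # plant the sweeps: the swept (alternate) allele rises by delta in the
    # domestic population; a fraction 1 - f_pi of sites lose polymorphism
    # outright, fixing at the nearer post-shift state. Retained sites are
    # capped just below fixation so they stay segregating and carry the
    # high between-population AF divergence of a hard sweep.
    for s in cfg.sweeps:
        m = (chroms == s.chrom) & (pos >= s.start) & (pos < s.end)
        d = af_d[m]
        shifted = np.minimum(d + s.delta, 1.0)
        fix = rng.random(d.size) >= s.f_pi
        af_d[m] = np.where(fix, np.round(shifted), np.minimum(shifted, 0.99))

    gt = np.empty((n_sites, n_tot), dtype=np.int8)
    gt[:, :cfg.n_domestic] = rng.binomial(
        2, af_d[:, None], size=(n_sites, cfg.n_domestic)
    )
    gt[:, cfg.n_domestic:] = rng.binomial(
        2, af_w[:, None], size=(n_sites, cfg.n_wild)
    )

    # drop sites monomorphic in the realized sample (never called as SNPs)
    poly = ~np.all(gt == gt[:, :1], axis=1)
    gt, chroms, pos = gt[poly], chroms[poly], pos[poly]
    n_sites = int(poly.sum())

    samples = [f"dom{i:03d}" for i in range(cfg.n_domestic)] + [
        f"wld{i:03d}" for i in range(cfg.n_wild)
    ]
    pops = np.array(["domestic"] * cfg.n_domestic + ["wild"] * cfg.n_wild)

    ref_i = rng.integers(0, 4, n_sites)
    alt_i = (ref_i + rng.integers(1, 4, n_sites)) % 4
    sample_mean_depth = np.clip(
        rng.normal(cfg.mean_depth, 1.5, n_tot), 6.0, None
    )
    depth = rng.poisson(sample_mean_depth[None, :], (n_sites, n_tot)).astype(
        np.int16
    )

    consequence = np.full(n_sites, None, dtype=object)
    labelled = rng.random(n_sites) < cfg.consequence_fraction
    consequence[labelled] = rng.choice(
        _CONSEQUENCES, size=int(labelled.sum()), p=_CONSEQUENCE_P
    )

    sites = pd.DataFrame(
        dict(
            chrom=chroms,
            pos=pos,
            pos1=pos + 1,
            ref=_BASES[ref_i],
            alt=_BASES[alt_i],
            qual=np.clip(rng.normal(60, 10, n_sites), 10, None).round(1),
            mq=np.clip(rng.normal(55, 3, n_sites), 10, None).round(1),
            bq=np.clip(rng.normal(33, 2, n_sites), 10, None).round(1),
            multiallelic=False,
            consequence=consequence,
        )
    )

    n_indels = int(rng.poisson(cfg.indel_rate_per_bp * L / 50))
    ind_off = np.sort(rng.choice(L, size=n_indels, replace=False))
    ind_ci = np.searchsorted(cum, ind_off, side="right") - 1
    indels = [
        (cfg.layout.names[c], int(ind_off[k] - cum[c]))
        for k, c in enumerate(ind_ci)
    ]
    return VariantTable(samples, pops, sites, gt, depth=depth, indels=indels)


# ---------------------------------------------------------------------------
# features, peaks, chains
# ---------------------------------------------------------------------------


def simulate_features(cfg: SimConfig, layout: GenomeLayout | None = None) -> dict:
    """Gene models plus promoter-proximal and distal regulatory features.

    Returns a dict of FeatureSets: gene, CDS, intron, UTR, TssA (active
    promoter at the TSS), Tx (transcribed gene body), EnhG (genic
    enhancer), Enh (distal enhancer), proximal, distal. Proximal classes
    sit near gene starts; Enh/distal classes are offset by the configured
    distances, so the median distance-to-TSS ordering of real annotation
    is reproduced.
    """
    layout = layout or cfg.layout
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]))
    sets = {
        k: [] for k in
        ("gene", "CDS", "intron", "UTR", "TssA", "Tx", "EnhG", "Enh",
         "proximal", "distal")
    }
    if cfg.n_genes == 0:
        return {
            k: FeatureSet(k, [], "gene_model" if k in
                          ("gene", "CDS", "intron", "UTR") else "roadmap_state")
            for k in sets
        }
    lens = np.array(layout.lengths, dtype=float)
    per_chrom = np.maximum(1, np.round(cfg.n_genes * lens / lens.sum()).astype(int))
    gid = 0
    for (chrom, clen), n_c in zip(layout.items(), per_chrom):
        margin = cfg.distal_offset + 10_000
        span = clen - 2 * margin
        if span <= 0 or n_c == 0:
            continue
        starts = np.sort(rng.choice(span // 1000, size=n_c, replace=False)) * 1000 + margin
        for s0 in starts:
            glen = int(rng.integers(5_000, 40_000))
            strand = "+" if rng.random() < 0.5 else "-"
            g_start, g_end = int(s0), int(s0) + glen
            name = f"GENE{gid:04d}"
            gid += 1
            sets["gene"].append(
                GenomicInterval(chrom, g_start, g_end, strand, name)
            )
            tss = g_start if strand == "+" else g_end
            # exon structure: UTR - CDS exons with introns - UTR
            n_ex = int(rng.integers(2, 6))
            cuts = np.sort(rng.choice(glen - 2, size=2 * n_ex - 1, replace=False)) + 1
            bounds = np.concatenate(([0], cuts, [glen])) + g_start
            for k in range(n_ex):
                sets["CDS"].append(
                    GenomicInterval(chrom, int(bounds[2 * k]), int(bounds[2 * k + 1]),
                                    strand, name)
                )
                if k < n_ex - 1:
                    sets["intron"].append(
                        GenomicInterval(chrom, int(bounds[2 * k + 1]),
                                        int(bounds[2 * k + 2]), strand, name)
                    )
            utr_len = int(rng.integers(100, 600))
            if g_start - utr_len > 0:
                sets["UTR"].append(
                    GenomicInterval(chrom, g_start - utr_len, g_start, strand, name)
                )
            sets["TssA"].append(
                GenomicInterval(
                    chrom,
                    max(0, tss - cfg.promoter_halfwidth),
                    tss + cfg.promoter_halfwidth,
                    strand, name,
                )
            )
            sets["Tx"].append(GenomicInterval(chrom, g_start, g_end, strand, name))
            # genic enhancer inside the body; distal enhancer offset from TSS
            if glen > 3000:
                es = int(rng.integers(g_start + 1000, g_end - 1500))
                sets["EnhG"].append(GenomicInterval(chrom, es, es + 1000, strand, name))
            off = int(rng.normal(cfg.enhancer_offset, cfg.enhancer_offset / 5))
            off = max(5_000, off) * (1 if rng.random() < 0.5 else -1)
            es = min(max(0, tss + off), clen - 1000)
            sets["Enh"].append(GenomicInterval(chrom, es, es + 1000, strand, name))
            ps = max(0, tss - cfg.proximal_offset)
            sets["proximal"].append(
                GenomicInterval(chrom, ps, ps + 1000, strand, name)
            )
            doff = int(rng.normal(cfg.distal_offset, cfg.distal_offset / 10))
            ds = min(max(0, tss + doff), clen - 800)
            sets["distal"].append(GenomicInterval(chrom, ds, ds + 800, strand, name))
    tags = dict.fromkeys(sets, "roadmap_state")
    for k in ("gene", "CDS", "intron", "UTR"):
        tags[k] = "gene_model"
    for k in ("proximal", "distal"):
        tags[k] = "encode_mark"
    return {k: FeatureSet(k, v, tags[k]) for k, v in sets.items()}


def simulate_peaks(
    predicted: FeatureSet,
    recovery: float,
    n_decoys: int,
    layout: GenomeLayout,
    seed,
    name: str = "peak",
) -> FeatureSet:
    """Experimental-style peaks recovering ~``recovery`` of ``predicted``.

    Each predicted interval is independently "recovered" with probability
    ``recovery`` by a peak centred on it (jittered width), then
    ``n_decoys`` unrelated peaks are placed uniformly.
    """
    if not (0 <= recovery <= 1):
        raise ValueError("recovery must be in [0, 1]")
    rng = np.random.default_rng(seed)
    peaks = []
    widths = []
    for iv in predicted:
        widths.append(len(iv))
        if rng.random() >= recovery:
            continue
        w = max(50, int(len(iv) * rng.uniform(0.6, 1.6)))
        centre = (iv.start + iv.end) // 2 + int(rng.integers(-len(iv) // 4,
                                                             len(iv) // 4 + 1))
        clen = layout.length_of(iv.chrom)
        start = max(0, min(centre - w // 2, clen - w))
        # anchor inside the source interval so overlap is guaranteed
        start = max(min(start, iv.end - 1), max(0, iv.start - w + 1))
        peaks.append(GenomicInterval(iv.chrom, start, start + w))
    med_w = int(np.median(widths)) if widths else 500
    cum = np.cumsum([0] + list(layout.lengths))
    for _ in range(n_decoys):
        g = int(rng.integers(0, layout.total_length))
        ci = int(np.searchsorted(cum, g, side="right") - 1)
        clen = layout.lengths[ci]
        w = min(med_w, clen - 1)
        start = int(rng.integers(0, clen - w))
        peaks.append(GenomicInterval(layout.names[ci], start, start + w))
    return FeatureSet(name, peaks, "chipseq_peak")


def simulate_chain(
    layout: GenomeLayout,
    indel_rate: float,
    seed,
    mean_indel_len: float = 20.0,
):
    """Pairwise alignment chains between ``layout`` and a synthetic donor.

    Walks each chromosome alternating aligned blocks (geometric length,
    mean 1/indel_rate) with short insertions or deletions, producing a
    forward ChainSet (analysis genome -> donor), the reciprocal ChainSet
    (donor -> analysis genome) and the donor layout. ``indel_rate`` 0
    yields identity chains.

    Returns
    -------
    (forward, backward, donor_layout)
    """
    rng = np.random.default_rng(seed)
    fwd, bwd = [], []
    donor = []
    cid = 1
    for chrom, clen in layout.items():
        qname = f"d_{chrom}"
        rows = []  # (size, dt, dq)
        t = q = 0
        while t < clen:
            if indel_rate <= 0:
                size = clen - t
            else:
                size = min(int(rng.geometric(indel_rate)), clen - t)
            t += size
            q += size
            if t >= clen:
                rows.append([size, 0, 0])
                break
            glen = 1 + int(rng.geometric(1.0 / mean_indel_len))
            if rng.random() < 0.5:  # deletion in donor: skip source bases
                glen = min(glen, clen - t - 1)
                if glen <= 0:
                    rows.append([size, 0, 0])
                    break
                rows.append([size, glen, 0])
                t += glen
            else:  # insertion in donor
                rows.append([size, 0, glen])
                q += glen
        qlen = q
        blocks = np.array(rows, dtype=np.int64)
        fwd.append(
            AlignmentChain(
                score=float(blocks[:, 0].sum()),
                t_name=chrom, t_size=clen, t_start=0, t_end=clen,
                q_name=qname, q_size=qlen, q_strand="+",
                q_start=0, q_end=qlen, chain_id=cid,
                blocks=blocks,
            )
        )
        bwd.append(
            AlignmentChain(
                score=float(blocks[:, 0].sum()),
                t_name=qname, t_size=qlen, t_start=0, t_end=qlen,
                q_name=chrom, q_size=clen, q_strand="+",
                q_start=0, q_end=clen, chain_id=cid,
                blocks=blocks[:, [0, 2, 1]].copy(),
            )
        )
        donor.append((qname, qlen))
        cid += 1
    fs, bs = ChainSet(fwd), ChainSet(bwd)
    fs.validate()
    bs.validate()
    return fs, bs, GenomeLayout.from_pairs(donor)


# ---------------------------------------------------------------------------
# hand-built QC showcase
# ---------------------------------------------------------------------------


def simulate_qc_showcase() -> VariantTable:
    """A hand-built 20-site table in which each QC rule fires exactly once.

    Fourteen diploid samples (8 domestic, 6 wild; the smallest even split
    for which a fully heterozygous site is rejected by the exact
    excess-heterozygosity test at p < 0.001); baseline sites have depth 10
    everywhere, MQ 60, BQ 33, full call rate, a balanced genotype mix and
    positions spaced 1 kb apart. Seven sites each violate exactly one rule
    of the post-calling filter cascade, in cascade order:

    1. ``depth``        pos 1000:  depth 2 in 8/14 samples
    2. ``map_base_quality`` pos 2000: MQ 20
    3. ``near_indel``   pos 3000:  an indel sits at pos 3003
    4. ``close_pair``   pos 4003:  3 bp from pos 4000, lower QUAL
    5. ``multiallelic`` pos 5000:  tri-allelic flag
    6. ``call_rate``    pos 6000:  2/14 genotypes missing (86%)
    7. ``hwe_excess_het`` pos 7000: all fourteen samples heterozygous
    """
    samples = [f"s{i}" for i in range(14)]
    pops = np.array(["domestic"] * 8 + ["wild"] * 6)
    n = 20
    # a balanced, HWE-compatible genotype column used for benign sites
    benign = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 0, 1, 0, 1], dtype=np.int8)
    gt = np.tile(benign, (n, 1)).copy()
    depth = np.full((n, 14), 10, dtype=np.int16)
    pos = np.arange(n) * 1000
    qual = np.full(n, 50.0)
    mq = np.full(n, 60.0)
    bq = np.full(n, 33.0)
    multi = np.zeros(n, dtype=bool)

    pos[:8] = [1000, 2000, 3000, 4000, 4003, 5000, 6000, 7000]
    pos[8:] = 8000 + np.arange(12) * 1000
    depth[0, :8] = 2          # (i) low depth in >50% of samples
    mq[1] = 20.0              # (ii) low mapping quality
    indels = [("chr1", 3003)]  # (iii) site at 3000 is within 5 bp
    qual[4] = 40.0            # (iv) lower-quality member of the 3 bp pair
    multi[5] = True           # (v) tri-allelic
    gt[6, 12:] = -1           # (vi) call rate 86%
    gt[7] = 1                 # (vii) every sample heterozygous

    sites = pd.DataFrame(
        dict(
            chrom="chr1",
            pos=pos,
            pos1=pos + 1,
            ref="A",
            alt="G",
            qual=qual,
            mq=mq,
            bq=bq,
            multiallelic=multi,
            consequence=None,
        )
    )
    return VariantTable(samples, pops, sites, gt, depth=depth, indels=indels)
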