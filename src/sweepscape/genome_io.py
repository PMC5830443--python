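"""Genome layouts, intervals, feature sets, alignment chains and flat-file I/O.

All internal coordinates are 0-based half-open. VCF positions (1-based) are
converted at the parsing boundary and the original position is kept in the
``pos1`` column of the site table. Chromosome names are matched by exact
string comparison; no "chr" aliasing is performed.

The interval arithmetic here (``intersect``, ``any_overlap``, ``closest``,
``shuffle``) re-implements the standard genome-arithmetic operations on
sorted numpy arrays so the rest of the pipeline has a single, well-tested
engine to build on.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "GenomicInterval",
    "FeatureSet",
    "AlignmentChain",
    "ChainSet",
    "VariantTable",
    "read_layout",
    "write_layout",
    "read_bed",
    "write_bed",
    "read_chain",
    "write_chain",
    "read_vcf",
    "write_vcf",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "intersect",
    "any_overlap",
    "overlaps_any",
    "closest",
    "shuffle",
]


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome name/length table.

    Parameters
    ----------
    names : tuple of str
        Chromosome names, unique, in genome order.
    lengths : tuple of int
        Chromosome lengths in bp, all positive.
    """

    names: tuple
    lengths: tuple

    def __post_init__(self):
        if len(self.names) != len(set(self.names)):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in count")

    @classmethod
    def from_pairs(cls, pairs):
        names, lengths = zip(*pairs) if pairs else ((), ())
        return cls(tuple(names), tuple(int(l) for l in lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[self.names.index(chrom)]
        except ValueError:
            raise KeyError(f"chromosome {chrom!r} not in layout") from None

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names

    def items(self):
        return zip(self.names, self.lengths)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class FeatureSet:
    """A named collection of genomic intervals of one feature class."""

    name: str
    intervals: list
    source_tag: str = ""

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    @property
    def total_length(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def chroms(self):
        return {iv.chrom for iv in self.intervals}

    def validate(self, layout: GenomeLayout) -> None:
        for iv in self.intervals:
            if iv.chrom not in layout:
                raise ValueError(f"{iv.chrom!r} not in layout")
            if iv.end > layout.length_of(iv.chrom):
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length"
                )

    def merged(self) -> "FeatureSet":
        """Union of the intervals: sorted, non-overlapping."""
        out = []
        for chrom in sorted(self.chroms()):
            ivs = sorted(
                (iv for iv in self.intervals if iv.chrom == chrom),
                key=lambda iv: (iv.start, iv.end),
            )
            cur_s, cur_e = ivs[0].start, ivs[0].end
            for iv in ivs[1:]:
                if iv.start <= cur_e:
                    cur_e = max(cur_e, iv.end)
                else:
                    out.append(GenomicInterval(chrom, cur_s, cur_e))
                    cur_s, cur_e = iv.start, iv.end
            out.append(GenomicInterval(chrom, cur_s, cur_e))
        return FeatureSet(self.name, out, self.source_tag)

    def merged_total_length(self) -> int:
        return self.merged().total_length if self.intervals else 0


@dataclass
class AlignmentChain:
    """One pairwise alignment chain (UCSC chain semantics).

    The chain maps coordinates FROM the ``t`` (source) genome TO the ``q``
    (target) genome. ``blocks`` is an (n, 3) int array of
    (aligned size, gap on source after block, gap on target after block);
    the final row has zero gaps. When ``q_strand`` is '-', q coordinates
    are expressed on the reversed target strand, as in the chain format.
    """

    score: float
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: int
    blocks: np.ndarray

    def validate(self) -> None:
        sizes = self.blocks[:, 0]
        dt = self.blocks[:, 1]
        dq = self.blocks[:, 2]
        if (sizes < 0).any() or (dt < 0).any() or (dq < 0).any():
            raise ValueError(f"chain {self.chain_id}: negative block field")
        if int(sizes.sum() + dt.sum()) != self.t_end - self.t_start:
            raise ValueError(
                f"chain {self.chain_id}: blocks do not tile source span"
            )
        if int(sizes.sum() + dq.sum()) != self.q_end - self.q_start:
            raise ValueError(
                f"chain {self.chain_id}: blocks do not tile target span"
            )

    def block_coords(self):
        """Source and target start positions of every aligned block.

        Returns (t_starts, q_starts, sizes); q positions are in the chain's
        own (possibly reversed) q frame.
        """
        sizes = self.blocks[:, 0]
        t_starts = self.t_start + np.concatenate(
            ([0], np.cumsum(sizes[:-1] + self.blocks[:-1, 1]))
        )
        q_starts = self.q_start + np.concatenate(
            ([0], np.cumsum(sizes[:-1] + self.blocks[:-1, 2]))
        )
        return t_starts, q_starts, sizes


@dataclass
class ChainSet:
    """A collection of alignment chains sharing a source/target genome pair."""

    chains: list = field(default_factory=list)

    def __len__(self):
        return len(self.chains)

    def __iter__(self):
        return iter(self.chains)

    def for_source_chrom(self, chrom: str):
        return [c for c in self.chains if c.t_name == chrom]

    def validate(self) -> None:
        for c in self.chains:
            c.validate()

    def target_layout(self) -> GenomeLayout:
        seen = {}
        for c in self.chains:
            seen.setdefault(c.q_name, c.q_size)
        return GenomeLayout(tuple(seen), tuple(seen.values()))


@dataclass
class VariantTable:
    """Per-site biallelic genotypes for two labelled populations.

    ``sites`` carries one row per site: chrom, pos (0-based), pos1 (the
    original 1-based position), ref, alt, qual, mq, bq, multiallelic and an
    optional consequence label. ``gt`` is an (n_sites, n_samples) int8
    matrix of alternate-allele dosages (0/1/2, -1 for missing).
    ``depth`` optionally carries per-site per-sample read depth, and
    ``indels`` the positions of indel records seen alongside the SNPs.
    """

    samples: list
    populations: np.ndarray  # str per sample: 'domestic' | 'wild'
    sites: pd.DataFrame
    gt: np.ndarray
    depth: np.ndarray | None = None
    indels: list = field(default_factory=list)

    def __post_init__(self):
        if self.gt.shape != (len(self.sites), len(self.samples)):
            raise ValueError("genotype matrix shape mismatch")
        self.populations = np.asarray(self.populations)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def pop_mask(self, population: str) -> np.ndarray:
        return self.populations == population

    def subset(self, row_mask: np.ndarray) -> "VariantTable":
        row_mask = np.asarray(row_mask)
        return VariantTable(
            samples=self.samples,
            populations=self.populations,
            sites=self.sites.loc[row_mask].reset_index(drop=True),
            gt=self.gt[row_mask],
            depth=None if self.depth is None else self.depth[row_mask],
            indels=list(self.indels),
        )

    def allele_frequency(self, population: str) -> np.ndarray:
        """Alternate-allele frequency per site; NaN where no calls."""
        g = self.gt[:, self.pop_mask(population)]
        called = g >= 0
        n_alleles = 2 * called.sum(axis=1)
        alt = np.where(called, g, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)


# ---------------------------------------------------------------------------
# flat-file readers / writers
# ---------------------------------------------------------------------------


def read_layout(path) -> GenomeLayout:
    """Read a two-column (name, length) TSV genome layout."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, length = line.split("\t")[:2]
            pairs.append((name, int(length)))
    return GenomeLayout.from_pairs(pairs)


def write_layout(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for name, length in layout.items():
            fh.write(f"{name}\t{length}\n")


def read_bed(path, class_name: str | None = None, source_tag: str = "") -> FeatureSet:
    """Read a BED3+ file into a FeatureSet (0-based half-open, as BED is)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval {start}-{end}"
                )
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(GenomicInterval(chrom, start, end, strand, name))
    import os

    cls = class_name or os.path.splitext(os.path.basename(str(path)))[0]
    return FeatureSet(cls, intervals, source_tag)


def write_bed(features: FeatureSet, path) -> None:
    """Write BED; emits BED6 when any interval carries a name or strand."""
    bed6 = any(iv.name or iv.strand != "." for iv in features)
    with open(path, "w") as fh:
        for iv in features:
            if bed6:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}"
                    f"\t0\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_chain(path) -> ChainSet:
    """Parse a UCSC chain-format file; block arithmetic is validated."""
    chains = []
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith("chain"):
            raise ValueError(f"{path}: expected chain header at line {i + 1}")
        parts = line.split()
        if len(parts) != 13:
            raise ValueError(f"{path}: malformed chain header at line {i + 1}")
        (_, score, t_name, t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end, chain_id) = parts
        if t_strand != "+":
            raise ValueError(f"{path}: chain {chain_id}: t strand must be '+'")
        i += 1
        rows = []
        closed = False
        while i < n:
            bl = lines[i].strip()
            i += 1
            if not bl:
                break
            fields = bl.split()
            if len(fields) == 3:
                rows.append([int(fields[0]), int(fields[1]), int(fields[2])])
            elif len(fields) == 1:
                rows.append([int(fields[0]), 0, 0])
                closed = True
                break
            else:
                raise ValueError(f"{path}: bad block line {i}")
        if not closed:
            raise ValueError(f"{path}: chain {chain_id} truncated")
        chain = AlignmentChain(
            score=float(score),
            t_name=t_name, t_size=int(t_size),
            t_start=int(t_start), t_end=int(t_end),
            q_name=q_name, q_size=int(q_size), q_strand=q_strand,
            q_start=int(q_start), q_end=int(q_end),
            chain_id=int(chain_id),
            blocks=np.array(rows, dtype=np.int64),
        )
        chain.validate()
        chains.append(chain)
    return ChainSet(chains)


def write_chain(chainset: ChainSet, path) -> None:
    with open(path, "w") as fh:
        for c in chainset:
            fh.write(
                f"chain {c.score:.0f} {c.t_name} {c.t_size} + "
                f"{c.t_start} {c.t_end} {c.q_name} {c.q_size} {c.q_strand} "
                f"{c.q_start} {c.q_end} {c.chain_id}\n"
            )
            for k, (size, dt, dq) in enumerate(c.blocks):
                if k == len(c.blocks) - 1:
                    fh.write(f"{size}\n")
                else:
                    fh.write(f"{size}\t{dt}\t{dq}\n")
            fh.write("\n")


_GT_CODE = {0: 0, 1: 1, 3: 2, 2: -1}  # cyvcf2 gt_types -> alt dosage


def read_vcf(path, population_map: dict) -> VariantTable:
    """Read a VCF 4.x into a VariantTable.

    ``population_map`` assigns every sample in the file to 'domestic' or
    'wild'; a sample missing from the map is a hard error. Indel records
    are collected into ``indels`` (they feed the QC proximity rule) and
    multi-allelic SNPs are retained but flagged for the QC cascade.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in population_map]
    if missing:
        raise ValueError(f"samples absent from population_map: {missing}")
    pops = np.array([population_map[s] for s in samples])

    rows, gts, indels = [], [], []
    n_bad_gt = 0
    for v in vcf:
        if v.is_indel:
            indels.append((v.CHROM, v.POS - 1))
            continue
        alts = v.ALT
        if not alts:
            continue
        info = dict(v.INFO)
        codes = np.array([_GT_CODE.get(t, -1) for t in v.gt_types], dtype=np.int8)
        n_bad_gt += int((v.gt_types == 2).sum())
        rows.append(
            dict(
                chrom=v.CHROM,
                pos=v.POS - 1,
                pos1=v.POS,
                ref=v.REF,
                alt=alts[0],
                qual=v.QUAL if v.QUAL is not None else np.nan,
                mq=float(info.get("MQ", np.nan)),
                bq=float(info.get("BQ", np.nan)),
                multiallelic=len(alts) > 1,
                consequence=str(info.get("CSQ", "")) or None,
            )
        )
        gts.append(codes)
    sites = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "pos1", "ref", "alt", "qual", "mq", "bq",
                 "multiallelic", "consequence"],
    )
    gt = np.vstack(gts) if gts else np.zeros((0, len(samples)), dtype=np.int8)
    table = VariantTable(samples, pops, sites, gt, indels=indels)
    table.sites.attrs["n_uncallable_gt"] = n_bad_gt
    return table


def write_vcf(table: VariantTable, path) -> None:
    """Write a minimal VCF 4.2 with GT fields and MQ/BQ/CSQ INFO keys."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##INFO=<ID=BQ,Number=1,Type=Float,Description="Mean base quality">\n')
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = table.sites["chrom"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples) + "\n"
        )
        code = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        for i, row in enumerate(table.sites.itertuples()):
            info = []
            if np.isfinite(row.mq):
                info.append(f"MQ={row.mq:g}")
            if np.isfinite(row.bq):
                info.append(f"BQ={row.bq:g}")
            if row.consequence:
                info.append(f"CSQ={row.consequence}")
            qual = f"{row.qual:g}" if np.isfinite(row.qual) else "."
            alt = f"{row.alt},T" if row.multiallelic and row.alt != "T" else (
                f"{row.alt},G" if row.multiallelic else row.alt
            )
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{alt}\t{qual}\t"
                f"PASS\t{';'.join(info) or '.'}\tGT\t"
                + "\t".join(code[int(g)] for g in table.gt[i]) + "\n"
            )


def write_genotype_matrix(table: VariantTable, path) -> None:
    """Compact TSV: chrom, pos1, ref, alt then one dosage column per sample."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\t" + "\t".join(table.samples) + "\n")
        for i, row in enumerate(table.sites.itertuples()):
            vals = "\t".join(
                "." if g < 0 else str(int(g)) for g in table.gt[i]
            )
            fh.write(f"{row.chrom}\t{row.pos1}\t{row.ref}\t{row.alt}\t{vals}\n")


def read_genotype_matrix(path, population_map: dict) -> VariantTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    samples = list(df.columns[4:])
    missing = [s for s in samples if s not in population_map]
    if missing:
        raise ValueError(f"samples absent from population_map: {missing}")
    gt = (
        df[samples]
        .replace(".", -1)
        .astype(np.int8)
        .to_numpy()
    )
    sites = pd.DataFrame(
        dict(
            chrom=df["chrom"],
            pos=df["pos"] - 1,
            pos1=df["pos"],
            ref=df["ref"],
            alt=df["alt"],
            qual=np.nan,
            mq=np.nan,
            bq=np.nan,
            multiallelic=False,
            consequence=None,
        )
    )
    pops = np.array([population_map[s] for s in samples])
    return VariantTable(samples, pops, sites, gt)


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------


def _by_chrom(features: FeatureSet):
    """chrom -> (starts, ends, original indices), sorted by start."""
    out = {}
    for chrom in features.chroms():
        idx = np.array(
            [i for i, iv in enumerate(features.intervals) if iv.chrom == chrom]
        )
        starts = np.array([features.intervals[i].start for i in idx])
        ends = np.array([features.intervals[i].end for i in idx])
        order = np.lexsort((ends, starts))
        out[chrom] = (starts[order], ends[order], idx[order])
    return out


def _merged_by_chrom(features: FeatureSet):
    m = features.merged()
    out = {}
    for chrom in m.chroms():
        ivs = [iv for iv in m if iv.chrom == chrom]
        out[chrom] = (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
        )
    return out


def _check_namespace(a: FeatureSet, b: FeatureSet) -> None:
    if len(a) and len(b) and not (a.chroms() & b.chroms()):
        raise ValueError(
            "feature sets share no chromosome names "
            f"({sorted(a.chroms())[:3]} vs {sorted(b.chroms())[:3]})"
        )


def overlaps_any(a: FeatureSet, b: FeatureSet) -> np.ndarray:
    """Boolean per a-interval: does it overlap >=1 bp of b?"""
    hits = np.zeros(len(a), dtype=bool)
    if not len(a) or not len(b):
        return hits
    merged = _merged_by_chrom(b)
    for i, iv in enumerate(a.intervals):
        mb = merged.get(iv.chrom)
        if mb is None:
            continue
        starts, ends = mb
        lo = np.searchsorted(ends, iv.start, side="right")
        hi = np.searchsorted(starts, iv.end, side="left")
        hits[i] = hi > lo
    return hits


def any_overlap(a: FeatureSet, b: FeatureSet) -> int:
    """Count of a-intervals touching at least one b-interval."""
    _check_namespace(a, b)
    return int(overlaps_any(a, b).sum())


def intersect(a: FeatureSet, b: FeatureSet) -> pd.DataFrame:
    """All pairwise overlaps between a and b.

    Returns a DataFrame with one row per overlapping (a, b) pair:
    a_index, b_index, chrom, start, end, overlap_bp.
    """
    _check_namespace(a, b)
    by_b = _by_chrom(b)
    rows = []
    for i, iv in enumerate(a.intervals):
        cb = by_b.get(iv.chrom)
        if cb is None:
            continue
        starts, ends, idx = cb
        hi = np.searchsorted(starts, iv.end, side="left")
        cand = np.nonzero(ends[:hi] > iv.start)[0]
        for k in cand:
            os_, oe = max(iv.start, starts[k]), min(iv.end, ends[k])
            rows.append((i, int(idx[k]), iv.chrom, int(os_), int(oe), int(oe - os_)))
    return pd.DataFrame(
        rows, columns=["a_index", "b_index", "chrom", "start", "end", "overlap_bp"]
    )


def closest(a: FeatureSet, b: FeatureSet) -> pd.DataFrame:
    """Nearest b-interval for each a-interval.

    Distance is 0 when the intervals overlap, otherwise the gap between the
    nearest ends, signed positive when b lies downstream of a. On
    chromosomes absent from b the distance is NaN (undefined, not 0). Ties
    go to the b-interval with the smaller start.
    """
    by_b = _by_chrom(b)
    rows = []
    for i, iv in enumerate(a.intervals):
        cb = by_b.get(iv.chrom)
        if cb is None:
            rows.append((i, -1, "", np.nan, np.nan))
            continue
        starts, ends, idx = cb
        pmax = np.maximum.accumulate(ends)
        # zero-distance candidates: overlapping or abutting on either side
        hi2 = np.searchsorted(starts, iv.end, side="right")
        zero = np.nonzero(ends[:hi2] >= iv.start)[0]
        cands = []  # (abs_dist, b_start, b_sorted_pos, signed)
        if zero.size:
            k = zero[np.argmin(starts[zero])]
            signed0 = 0
            if starts[k] >= iv.end:
                signed0 = 0  # abutting right; gap is 0 either way
            cands.append((0, int(starts[k]), int(k), signed0))
        hi = np.searchsorted(starts, iv.end, side="left")
        if hi > 0 and pmax[hi - 1] < iv.start:  # nearest strictly left
            gap = iv.start - int(pmax[hi - 1])
            k = int(np.argmax(ends[:hi] == pmax[hi - 1]))
            cands.append((gap, int(starts[k]), k, -gap))
        if hi2 < len(starts) and starts[hi2] > iv.end:  # strictly right
            gap = int(starts[hi2]) - iv.end
            cands.append((gap, int(starts[hi2]), int(hi2), gap))
        if not cands:
            # only possible when every interval is strictly right of iv
            # with start > iv.end handled above; defensive fallback
            k = 0
            gap = int(starts[0]) - iv.end
            cands.append((gap, int(starts[0]), 0, gap))
        _, _, k, signed = min(cands, key=lambda c: (c[0], c[1]))
        j = int(idx[k])
        rows.append((i, j, b.intervals[j].name, float(signed), float(abs(signed))))
    return pd.DataFrame(
        rows, columns=["a_index", "b_index", "b_name", "distance", "abs_distance"]
    )


def shuffle(
    features: FeatureSet,
    layout: GenomeLayout,
    seed,
    max_tries: int = 1000,
) -> FeatureSet:
    """Random uniform re-placement of the intervals, non-overlapping.

    Each interval keeps its length and is dropped anywhere on the genome
    (any chromosome, chosen with probability proportional to length) such
    that no two placed intervals overlap. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    if features.total_length >= layout.total_length:
        raise ValueError("total feature length exceeds genome length")
    cum = np.cumsum([0] + list(layout.lengths))
    placed_s = {c: [] for c in layout.names}
    placed_e = {c: [] for c in layout.names}
    out = []
    for iv in features.intervals:
        L = len(iv)
        for _ in range(max_tries):
            g = int(rng.integers(0, layout.total_length))
            ci = int(np.searchsorted(cum, g, side="right") - 1)
            chrom = layout.names[ci]
            clen = layout.lengths[ci]
            if clen < L:
                continue
            start = int(rng.integers(0, clen - L + 1))
            end = start + L
            ss, ee = placed_s[chrom], placed_e[chrom]
            j = bisect.bisect_right(ss, start)
            if (j > 0 and ee[j - 1] > start) or (j < len(ss) and ss[j] < end):
                continue
            ss.insert(j, start)
            ee.insert(j, end)
            out.append(GenomicInterval(chrom, start, end, iv.strand, iv.name))
            break
        else:
            raise RuntimeError(
                f"could not place a {L} bp interval after {max_tries} tries"
            )
    return FeatureSet(features.name, out, features.source_tag)
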