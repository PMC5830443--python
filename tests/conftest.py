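import numpy as np
import pandas as pd
import pytest

from sweepscape.genome_io import FeatureSet, GenomeLayout, GenomicInterval, VariantTable


def make_table(gt_dom, gt_wild, positions=None, chrom="chr1", **site_cols):
    """Build a VariantTable from dosage matrices (sites x samples)."""
    gt_dom = np.asarray(gt_dom, dtype=np.int8)
    gt_wild = np.asarray(gt_wild, dtype=np.int8)
    n = gt_dom.shape[0]
    gt = np.hstack([gt_dom, gt_wild])
    samples = [f"d{i}" for i in range(gt_dom.shape[1])] + [
        f"w{i}" for i in range(gt_wild.shape[1])
    ]
    pops = np.array(
        ["domestic"] * gt_dom.shape[1] + ["wild"] * gt_wild.shape[1]
    )
    pos = np.asarray(positions) if positions is not None else np.arange(n) * 1000
    sites = pd.DataFrame(
        dict(
            chrom=chrom,
            pos=pos,
            pos1=pos + 1,
            ref="A",
            alt="G",
            qual=site_cols.get("qual", np.full(n, 50.0)),
            mq=site_cols.get("mq", np.full(n, 60.0)),
            bq=site_cols.get("bq", np.full(n, 33.0)),
            multiallelic=site_cols.get("multiallelic", np.zeros(n, bool)),
            consequence=site_cols.get("consequence", [None] * n),
        )
    )
    return VariantTable(samples, pops, sites, gt)


def random_feature_set(rng, layout, n, max_len=500, name="rand"):
    ivs = []
    for _ in range(n):
        ci = rng.integers(0, len(layout.names))
        chrom, clen = layout.names[ci], layout.lengths[ci]
        L = int(rng.integers(1, max_len))
        s = int(rng.integers(0, clen - L))
        ivs.append(GenomicInterval(chrom, s, s + L))
    return FeatureSet(name, ivs)


@pytest.fixture
def tiny_layout():
    return GenomeLayout(("chr1", "chr2"), (100_000, 50_000))


@pytest.fixture(scope="session")
def default_sim():
    """One shared realisation of the default synthetic genome (seed 7)."""
    from sweepscape.synthetic_data import default_config, simulate_variants

    cfg = default_config(seed=7)
    return cfg, simulate_variants(cfg)
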