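"""Configuration-driven orchestration of the full analysis chain.

Stages run in dependency order:

    simulate -> qc -> project -> scan -> validate -> enrich -> deltaaf

``simulate`` generates genotypes on the analysis genome, annotation
features on a synthetic donor genome and the reciprocal alignment chains
between the two. ``project`` transfers the donor features onto the
analysis genome (minMatch + reciprocal filter); the projected features
feed gene assignment, peak validation, sweep-bin enrichment and the dAF
M-value analysis. Every output is a TSV/BED/VCF text file listed in a
manifest with its SHA-256, and a rerun with the same configuration and
seed reproduces the files byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allele_divergence as ad
from . import enrichment as en
from . import sweep_scan as scan
from . import synthetic_data as syn
from .comparative_annotation import reciprocal_map
from .genome_io import FeatureSet, write_bed, write_chain, write_layout, write_vcf
from .variant_qc import QcParams, apply_qc

log = logging.getLogger("sweepscape")

__all__ = ["PipelineConfig", "run"]

STAGES = ("simulate", "qc", "project", "scan", "validate", "enrich", "deltaaf")


@dataclass
class PipelineConfig:
    out_dir: str = "sweepscape_out"
    seed: int = 0
    stages: tuple = STAGES
    # scan parameters
    bin_size: int = 20_000
    step: int = 10_000
    min_snp: int = 20
    alpha: float = 0.001
    merge_gap: int = 50_000
    # projection
    min_match: float = 0.1
    min_back_overlap: float = 0.5
    chain_indel_rate: float = 2e-5
    # validation
    n_shuffles: int = 200
    peak_recovery_promoter: float = 0.85
    peak_recovery_enhancer: float = 0.71
    n_decoy_peaks: int = 300
    # dAF analysis
    daf_bin_width: float = 0.1
    daf_threshold: float = 0.8
    perturb_delta: float = 0.0  # > 0 also runs the exonic control
    # simulation overrides (merged into the default SimConfig)
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        cfg.stages = tuple(cfg.stages)
        return cfg

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        d = asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def sim_config(self) -> syn.SimConfig:
        base = syn.default_config(seed=self._stage_seed(0))
        overrides = dict(self.sim)
        if "layout" in overrides:
            from .genome_io import GenomeLayout

            overrides["layout"] = GenomeLayout.from_pairs(
                [tuple(p) for p in overrides["layout"]]
            )
        if "sweeps" in overrides:
            overrides["sweeps"] = [syn.SweepSpec(**s) for s in overrides["sweeps"]]
        from dataclasses import replace

        return replace(base, **overrides)

    def _stage_seed(self, k: int) -> int:
        return int((self.seed + 1_000_003 * (k + 1)) % (2**31 - 1))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns the output manifest dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    state: dict = {}
    t0 = time.time()

    def emit(path: Path):
        outputs.append(path)

    def stage_on(name: str) -> bool:
        if name not in cfg.stages:
            log.info("stage %s: skipped (toggled off)", name)
            return False
        log.info("stage %s: running", name)
        return True

    try:
        _run_stages(cfg, out, state, emit, stage_on)
    except Exception:
        marker = out / "FAILED"
        marker.write_text("pipeline aborted; partial outputs retained\n")
        raise

    manifest = dict(
        config_hash=cfg.config_hash(),
        seed=cfg.seed,
        elapsed_s=round(time.time() - t0, 2),
        outputs={str(p.relative_to(out)): _sha256(p) for p in outputs},
        results=state.get("summary", {}),
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _run_stages(cfg, out, state, emit, stage_on):
    summary = state.setdefault("summary", {})

    # ------------------------------------------------------------ simulate
    if stage_on("simulate"):
        sim = cfg.sim_config()
        state["sim"] = sim
        variants = syn.simulate_variants(sim)
        fwd, bwd, donor_layout = syn.simulate_chain(
            sim.layout, cfg.chain_indel_rate, seed=cfg._stage_seed(1)
        )
        donor_features = syn.simulate_features(sim, layout=donor_layout)
        state.update(
            variants=variants, fwd=fwd, bwd=bwd,
            donor_layout=donor_layout, donor_features=donor_features,
        )
        write_layout(sim.layout, out / "genome.tsv")
        emit(out / "genome.tsv")
        write_vcf(variants, out / "variants.vcf")
        emit(out / "variants.vcf")
        write_chain(fwd, out / "analysis_to_donor.chain")
        emit(out / "analysis_to_donor.chain")
        write_chain(bwd, out / "donor_to_analysis.chain")
        emit(out / "donor_to_analysis.chain")
        for name, fs in donor_features.items():
            p = out / f"donor_{name}.bed"
            write_bed(fs, p)
            emit(p)
        truth = FeatureSet(
            "sweep_truth",
            [syn.GenomicInterval(s.chrom, s.start, s.end) for s in sim.sweeps],
        )
        write_bed(truth, out / "sweep_truth.bed")
        emit(out / "sweep_truth.bed")
        summary["n_sites_simulated"] = variants.n_sites

    # ------------------------------------------------------------------ qc
    if stage_on("qc"):
        filtered, report = apply_qc(state["variants"], QcParams())
        state["variants_qc"] = filtered
        _write_tsv(report.to_frame(), out / "qc_report.tsv")
        emit(out / "qc_report.tsv")
        summary["n_sites_after_qc"] = filtered.n_sites
    else:
        state["variants_qc"] = state["variants"]

    # ------------------------------------------------------------- project
    if stage_on("project"):
        projected = {}
        status_rows = []
        for name, fs in state["donor_features"].items():
            kept, fwd_res = reciprocal_map(
                fs, state["bwd"], state["fwd"],
                min_match=cfg.min_match,
                min_back_overlap=cfg.min_back_overlap,
            )
            projected[name] = kept
            for r in fwd_res:
                status_rows.append(
                    dict(feature=name, chrom=r.source.chrom,
                         start=r.source.start, end=r.source.end,
                         status=r.status, fraction=round(r.fraction, 4))
                )
            p = out / f"predicted_{name}.bed"
            write_bed(kept, p)
            emit(p)
        state["features"] = projected
        _write_tsv(pd.DataFrame(status_rows), out / "projection_status.tsv")
        emit(out / "projection_status.tsv")
        summary["n_features_projected"] = int(
            sum(len(f) for f in projected.values())
        )

    # ---------------------------------------------------------------- scan
    if stage_on("scan"):
        sim = state["sim"]
        w = scan.window_stats(
            state["variants_qc"], sim.layout,
            bin_size=cfg.bin_size, step=cfg.step, min_snp=cfg.min_snp,
        )
        w, thresholds = scan.call_outliers(w, alpha=cfg.alpha)
        _write_tsv(w, out / "window_stats.tsv")
        emit(out / "window_stats.tsv")
        flagged = w[w["outlier"] & (w["direction"] == "domestic")]
        regions = scan.merge_regions(flagged, gap=cfg.merge_gap)
        genes = state.get("features", {}).get("gene")
        if genes is not None and len(genes):
            scan.assign_genes(regions, genes)
        reg_df = pd.DataFrame(
            dict(
                chrom=[r.chrom for r in regions],
                start=[r.start for r in regions],
                end=[r.end for r in regions],
                n_bins=[r.n_bins for r in regions],
                peak_z_fst=[round(r.peak_z_fst, 3) for r in regions],
                gene=[r.gene for r in regions],
                gene_distance=[r.gene_distance for r in regions],
            )
        )
        _write_tsv(reg_df, out / "sweep_regions.tsv")
        emit(out / "sweep_regions.tsv")
        bins_fs = FeatureSet(
            "outlier_bins",
            [syn.GenomicInterval(r.chrom, r.start, r.end)
             for r in flagged.itertuples()],
            "sweep_bin",
        )
        write_bed(bins_fs, out / "outlier_bins.bed")
        emit(out / "outlier_bins.bed")
        state.update(windows=w, flagged=flagged, regions=regions)
        shared = scan.shared_polymorphism_summary(state["variants_qc"])
        r_af, p_af, n_af = scan.af_correlation(state["variants_qc"])
        summary.update(
            thresholds={k: round(v, 4) for k, v in thresholds.items()},
            n_outlier_bins=int(flagged.shape[0]),
            n_regions=len(regions),
            mean_region_size_kb=(
                round(float(np.mean([r.size for r in regions])) / 1000, 2)
                if regions else float("nan")
            ),
            genome_mean_fst=round(float(np.nanmean(w["mean_fst"])), 4),
            pi_domestic=float(np.nanmean(w["pi_dom"])),
            pi_wild=float(np.nanmean(w["pi_wild"])),
            shared_polymorphism=shared,
            af_correlation=dict(r=round(r_af, 4), n=n_af),
        )

    # ------------------------------------------------------------ validate
    if stage_on("validate"):
        sim = state["sim"]
        feats = state["features"]
        rows = []
        peaks = {}
        for name, r in (
            ("TssA", cfg.peak_recovery_promoter),
            ("Enh", cfg.peak_recovery_enhancer),
        ):
            fs = feats[name]
            if not len(fs):
                continue
            pk = syn.simulate_peaks(
                fs, r, cfg.n_decoy_peaks, sim.layout,
                seed=cfg._stage_seed(3 if name == "TssA" else 4),
                name=f"{name}_peaks",
            )
            peaks[name] = pk
            write_bed(pk, out / f"peaks_{name}.bed")
            emit(out / f"peaks_{name}.bed")
            rec = en.recovery_rate(fs, pk)
            emp = en.empirical_overlap_p(
                fs, pk, sim.layout, n=cfg.n_shuffles,
                seed=cfg._stage_seed(5),
            )
            rows.append(
                dict(feature=name, n_predicted=rec.n_query,
                     n_recovered=rec.n_hit, percent=rec.percent,
                     empirical_p=emp.p, null_mean=round(emp.null_mean, 2))
            )
        val = pd.DataFrame(rows)
        _write_tsv(val, out / "validation.tsv")
        emit(out / "validation.tsv")
        state["peaks"] = peaks
        summary["recovery"] = {
            r["feature"]: r["percent"] for r in rows
        }
        summary["validation_empirical_p"] = {
            r["feature"]: r["empirical_p"] for r in rows
        }

    # -------------------------------------------------------------- enrich
    if stage_on("enrich"):
        w = state["windows"]
        universe = FeatureSet(
            "universe",
            [syn.GenomicInterval(r.chrom, r.start, r.end)
             for r in w[~w["masked"]].itertuples()],
            "sweep_bin",
        )
        reference = FeatureSet(
            "reference",
            [syn.GenomicInterval(r.chrom, r.start, r.end)
             for r in state["flagged"].itertuples()],
            "sweep_bin",
        )
        queries = {
            n: f for n, f in state["features"].items() if len(f) and n != "gene"
        }
        for n, pk in state.get("peaks", {}).items():
            queries[f"{n}_peaks"] = pk
        enr = en.locus_overlap_enrichment(queries, reference, universe)
        _write_tsv(enr, out / "enrichment.tsv")
        emit(out / "enrichment.tsv")
        state["enrichment"] = enr
        summary["top_enrichment"] = {
            r.feature: round(r.neg_log10_p, 2)
            for r in enr.head(3).itertuples()
        }

    # ------------------------------------------------------------- deltaaf
    if stage_on("deltaaf"):
        v = state["variants_qc"]
        daf = ad.delta_af(v)
        feats = {
            n: f for n, f in state["features"].items() if len(f)
        }
        tab = ad.mvalue_table(daf, feats, bin_width=cfg.daf_bin_width)
        m_out = tab.m.copy()
        m_out.columns = tab.bin_labels()
        m_out.insert(0, "feature", m_out.index)
        _write_tsv(m_out, out / "daf_mvalues.tsv")
        emit(out / "daf_mvalues.tsv")
        _write_tsv(tab.chi2, out / "daf_chi2.tsv")
        emit(out / "daf_chi2.tsv")
        counts, high = ad.consequence_scan(v, daf, threshold=cfg.daf_threshold)
        _write_tsv(high, out / "daf_high_sites.tsv")
        emit(out / "daf_high_sites.tsv")
        summary["n_shared_sites"] = int(len(daf))
        summary["n_high_daf"] = int(len(high))
        summary["high_daf_consequences"] = {
            str(k): int(c) for k, c in counts.items()
        }
        if cfg.perturb_delta > 0 and "CDS" in feats:
            pert = ad.perturb_exonic_af(
                daf, feats["CDS"], cfg.perturb_delta,
                seed=cfg._stage_seed(6),
            )
            ptab = ad.mvalue_table(pert, feats, bin_width=cfg.daf_bin_width)
            p_out = ptab.m.copy()
            p_out.columns = ptab.bin_labels()
            p_out.insert(0, "feature", p_out.index)
            _write_tsv(p_out, out / "daf_mvalues_perturbed.tsv")
            emit(out / "daf_mvalues_perturbed.tsv")
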