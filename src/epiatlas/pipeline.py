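"""End-to-end orchestration of the synthetic epigenome-map analysis.

``run_demo`` reproduces the full analysis flow on a seeded toy genome:
simulate mark tracks from a known chromatin-state model, binarize raw
counts, segment with the model, call UMR/LMR methylome regions, classify
expressed/repressed and tissue-specific genes, build a cross-epigenome
enhancer atlas with tissue-specific enhancers, and test GWAS-SNP enhancer
enrichment.  Outputs are plain BED/TSV files; every file carries a header
with the package version, the resolved-config hash and the seed, and reruns
with the same seed are byte-identical.

All randomness flows from one root seed, split deterministically per stage.
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

from . import __version__
from .chromatin import binarize_track, save_chromhmm_model, segment, state_coverage
from .enhancers import (
    build_presence_matrix,
    link_genes_to_enhancers,
    shared_fraction,
    specific_enhancers,
)
from .expression import classify_genes, fit_gmm2, log_transform, tissue_specificity
from .genome import write_bed
from .gwas import enhancer_enrichment, filter_studies, prune_catalog, results_to_frame
from .methylome import (
    MethylSegConfig,
    filter_coverage,
    regions_to_intervals,
    segment_hypomethylated,
    write_cpg_table,
)
from .simulate import (
    example_model,
    simulate_assembly,
    simulate_epigenome_panel,
    simulate_expression,
    simulate_genes,
    simulate_gwas_catalog,
    simulate_marks,
    simulate_methylome,
    simulate_raw_tracks,
)

logger = logging.getLogger("epiatlas")

__all__ = ["PipelineConfig", "run_demo", "stage_seed"]


@dataclass
class PipelineConfig:
    """Resolved parameters of a pipeline run (written beside every output)."""

    bin_size: int = 200
    binarization_p: float = 1e-4
    n_states: int = 5
    enhancer_states: tuple[str, ...] = ("9_EnhA1", "10_EnhA2")
    meth_min_coverage: int = 5
    meth_threshold: float = 0.5
    meth_min_cpgs: int = 5
    meth_fdr: float = 0.05
    gmm_posterior_cutoff: float = 0.9
    specificity_fold: float = 4.0
    specificity_group: tuple[int, int] = (2, 5)
    specificity_min_tpm: float = 1.0
    link_flank: int = 20_000
    prune_distance: int = 1_000_000
    min_study_snps: int = 2
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.bin_size < 1:
            problems.append("bin_size must be >= 1")
        if not 0 < self.binarization_p < 1:
            problems.append("binarization_p must lie in (0, 1)")
        if not 0 < self.meth_threshold < 1:
            problems.append("meth_threshold must lie in (0, 1)")
        if self.gmm_posterior_cutoff <= 0.5:
            problems.append("gmm_posterior_cutoff must exceed 0.5")
        if self.specificity_fold <= 1:
            problems.append("specificity_fold must exceed 1")
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("enhancer_states", "specificity_group"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["enhancer_states"] = list(data["enhancer_states"])
        data["specificity_group"] = list(data["specificity_group"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministically derive a per-stage seed below 2**31 from the root seed."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _header(cfg: PipelineConfig) -> str:
    return f"epiatlas v{__version__} config={cfg.config_hash()} seed={cfg.seed}"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"#{_header(cfg)}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def run_demo(outdir: str | Path, config: PipelineConfig | None = None) -> dict:
    """Run the full synthetic analysis; returns a manifest of key numbers.

    Writes segmentation BED, UMR/LMR BED, gene class and specificity TSVs,
    specific-enhancer BED, GWAS enrichment TSV, the resolved config and a
    JSON run manifest under ``outdir``.
    """
    cfg = config or PipelineConfig()
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {"version": __version__, "seed": cfg.seed, "config": cfg.config_hash()}
    cfg.to_yaml(outdir / "config.yaml")

    # --- chromatin states on the toy genome -------------------------------
    assembly = simulate_assembly()
    model = example_model(cfg.n_states)
    save_chromhmm_model(model, outdir / "model.txt")
    tracks, true_states, bins = simulate_marks(
        model, assembly, stage_seed(cfg.seed, "marks"), cfg.bin_size
    )
    raw = simulate_raw_tracks(tracks, stage_seed(cfg.seed, "counts"))
    binarized = [binarize_track(t, p_threshold=cfg.binarization_p) for t in raw]
    seg = segment(binarized, model)
    seg.to_bed(outdir / "segmentation.bed", header=_header(cfg))
    coverage = state_coverage(seg)
    manifest["state_recovery"] = float((seg.states == true_states).mean())
    manifest["state_coverage"] = {k: float(v) for k, v in coverage.items()}
    logger.info("segmentation: %.1f%% of bins recover the generating state",
                100 * manifest["state_recovery"])

    # --- methylome --------------------------------------------------------
    cpgs, meth_truth = simulate_methylome(
        assembly, n_cpgs=20_000, seed=stage_seed(cfg.seed, "methylome"), n_planted=20
    )
    write_cpg_table(cpgs, outdir / "cpg_counts.tsv", header=_header(cfg))
    retained = filter_coverage(cpgs, cfg.meth_min_coverage)
    regions, chosen_n, fdr = segment_hypomethylated(
        retained,
        MethylSegConfig(
            min_coverage=cfg.meth_min_coverage,
            meth_threshold=cfg.meth_threshold,
            min_cpgs=cfg.meth_min_cpgs,
            fdr_target=cfg.meth_fdr,
            seed=stage_seed(cfg.seed, "methylome-fdr"),
        ),
    )
    write_bed(regions_to_intervals(regions, assembly), outdir / "umr_lmr.bed",
              header=_header(cfg))
    manifest["methylome"] = {
        "n_regions": len(regions),
        "n_umr": sum(r.klass == "UMR" for r in regions),
        "n_lmr": sum(r.klass == "LMR" for r in regions),
        "chosen_min_cpgs": chosen_n,
        "achieved_fdr": None if np.isnan(fdr) else float(fdr),
        "n_planted": len(meth_truth.planted),
    }

    # --- expression -------------------------------------------------------
    expr, expr_truth = simulate_expression(seed=stage_seed(cfg.seed, "expression"))
    mean_log = log_transform(expr).mean(axis=1).to_numpy()
    fit = fit_gmm2(mean_log, seed=stage_seed(cfg.seed, "gmm"))
    classes = classify_genes(fit, mean_log, cfg.gmm_posterior_cutoff, gene_ids=expr.index)
    _write_tsv(classes, outdir / "gene_classes.tsv", cfg)
    calls = tissue_specificity(
        expr, "prostate", cfg.specificity_fold, cfg.specificity_group, cfg.specificity_min_tpm
    )
    _write_tsv(calls, outdir / "tissue_specificity.tsv", cfg)
    manifest["expression"] = {
        "gmm_means": [float(v) for v in fit.means],
        "gmm_weights": [float(v) for v in fit.weights],
        "n_expressed": int((classes["klass"] == "expressed").sum()),
        "n_repressed": int((classes["klass"] == "repressed").sum()),
        "n_ambiguous": int((classes["klass"] == "ambiguous").sum()),
        "n_specific": int((calls["category"] != "not-specific").sum()),
    }

    # --- enhancer atlas ---------------------------------------------------
    segs, panel_truth, panel_bins = simulate_epigenome_panel(
        assembly, seed=stage_seed(cfg.seed, "panel")
    )
    target_epigenome = next(iter(panel_truth.specific_bins))
    pm = build_presence_matrix(segs, ("9_EnhA1",))
    spec_enh = specific_enhancers(pm, target_epigenome)
    write_bed(spec_enh, outdir / "specific_enhancers.bed", header=_header(cfg))
    genes = simulate_genes(assembly, seed=stage_seed(cfg.seed, "genes"))
    linked, linked_fraction = link_genes_to_enhancers(genes, spec_enh, cfg.link_flank)
    manifest["atlas"] = {
        "target": target_epigenome,
        "n_specific_enhancers": len(spec_enh),
        "shared_fraction": shared_fraction(pm),
        "linked_gene_fraction": linked_fraction,
    }

    # --- GWAS enrichment --------------------------------------------------
    catalog, gwas_truth = simulate_gwas_catalog(
        simulate_assembly(4, [20_000_000] * 4),
        n_studies=30,
        seed=stage_seed(cfg.seed, "gwas"),
        snps_per_study=(15, 25),
        enriched_studies={"study0001": 0.8},
    )
    pruned = prune_catalog(filter_studies(catalog, cfg.min_study_snps), cfg.prune_distance)
    results = results_to_frame(
        enhancer_enrichment(pruned, gwas_truth.enhancers, target_epigenome)
    )
    _write_tsv(results, outdir / "gwas_enrichment.tsv", cfg)
    best = results.loc[results["p"].idxmin()]
    manifest["gwas"] = {
        "n_studies": int(len(results)),
        "min_p_study": str(best["study"]),
        "min_p": float(best["p"]),
    }

    manifest["runtime_s"] = round(time.time() - t0, 2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("demo finished in %.1f s", manifest["runtime_s"])
    return manifest
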