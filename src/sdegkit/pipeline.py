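"""End-to-end pipeline: counts -> SS -> thresholds -> calls -> enrichment.

The stage order is the one the calling method prescribes: optional
low-count filtering and median-ratio normalization of a raw count matrix;
SS scoring of the DE results table; per-side two-means threshold
derivation; SDEG calling; background-restricted ORA (with ESS and weighted
set cover) and pre-ranked GSEA; a matched random-list calibration; and an
optional meta-signature comparison.  Every output is a tab-separated table
plus a JSON run manifest recording inputs, seeds, derived thresholds and
the gene counts at each filter boundary, so a run is reproducible from the
manifest alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as skio
from .enrich import preranked_gsea, ora, weighted_set_cover
from .errors import ConfigurationError
from .nullmeta import (
    RandomListSpec,
    calibration_experiment,
    combine_meta_mission,
    generate_random_lists,
    intersect_signature,
    proportion_chisq,
)
from .sdeg import (
    DEFAULT_ALPHA,
    DEFAULT_PADJ_FLOOR,
    call_sdegs,
    compute_significance_scores,
    derive_ss_thresholds,
    filter_low_counts,
    median_ratio_normalize,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, cutoffs and seeds of one pipeline run.

    ``de_table`` is mandatory (the pipeline consumes upstream DE output);
    ``counts`` only adds the preprocessing stage; ``gmt`` enables ORA/GSEA;
    ``background`` defaults to every gene in the DE table.  All stochastic
    stages (Lloyd clustering, GSEA permutations, calibration draws) run off
    the explicit ``seed``.
    """

    de_table: str
    out_dir: str
    counts: str | None = None
    gmt: str | None = None
    background: str | None = None
    meta_lists: dict[str, str] = field(default_factory=dict)

    alpha: float = DEFAULT_ALPHA
    fdr_cutoff: float = 0.05
    clustering_method: str = "exact"
    seed: int = 0
    padj_floor: float = DEFAULT_PADJ_FLOOR
    low_count_threshold: float = 10.0
    ess_report_min: float = 10.0
    ora_test: str = "hypergeometric"
    run_gsea: bool = True
    gsea_n_perm: int = 1000
    gsea_min_size: int = 5
    calibration_replicates: int = 0

    def validate(self) -> None:
        for label, path in [
            ("de_table", self.de_table),
            ("counts", self.counts),
            ("gmt", self.gmt),
            ("background", self.background),
            *[(f"meta_lists[{k}]", v) for k, v in self.meta_lists.items()],
        ]:
            if path is not None and not Path(path).exists():
                raise ConfigurationError(f"{label} path does not exist: {path}")
        if not isinstance(self.seed, int):
            raise ConfigurationError("seed must be an explicit integer")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage; write tables and a run manifest.

    Returns a bundle dict with the in-memory results (thresholds, call set,
    reports) keyed by stage name.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "inputs": {
            "de_table": str(config.de_table),
            "counts": config.counts and str(config.counts),
            "gmt": config.gmt and str(config.gmt),
            "background": config.background and str(config.background),
            "meta_lists": {k: str(v) for k, v in config.meta_lists.items()},
        },
        "parameters": {
            "alpha": config.alpha,
            "fdr_cutoff": config.fdr_cutoff,
            "clustering_method": config.clustering_method,
            "seed": config.seed,
            "padj_floor": config.padj_floor,
            "low_count_threshold": config.low_count_threshold,
            "ora_test": config.ora_test,
            "gsea_n_perm": config.gsea_n_perm,
            "gsea_min_size": config.gsea_min_size,
            "calibration_replicates": config.calibration_replicates,
        },
        "stages": {},
        "outputs": [],
    }
    bundle: dict = {}

    def _write(frame: pd.DataFrame, name: str, writer=skio.write_tsv):
        path = out_dir / name
        writer(frame, path)
        manifest["outputs"].append(name)

    # --- counts preprocessing -------------------------------------------
    if config.counts is not None:
        counts = skio.read_counts(config.counts)
        filtered = filter_low_counts(counts, config.low_count_threshold)
        normalized = median_ratio_normalize(filtered)
        manifest["stages"]["counts"] = {
            "genes_in": int(counts.shape[0]),
            "genes_dropped_low_count": int(counts.shape[0] - filtered.shape[0]),
            "genes_out": int(filtered.shape[0]),
            "size_factors": {
                s: float(v) for s, v in normalized.size_factors.items()
            },
        }
        logger.info(
            "counts: %d genes in, %d dropped below mean %g, %d out",
            counts.shape[0], counts.shape[0] - filtered.shape[0],
            config.low_count_threshold, filtered.shape[0],
        )
        _write(normalized.matrix.rename_axis("gene_id").reset_index(),
               "normalized_counts.tsv")
        bundle["normalized_counts"] = normalized

    # --- SS scoring and SDEG calling ------------------------------------
    de_table = skio.read_de_table(config.de_table)
    eligible = skio.ss_eligible(de_table)
    n_na = int((~eligible).sum())
    if n_na:
        logger.info("de table: %d rows with NA padj/LFC excluded from SS scoring", n_na)
    scored = de_table[eligible].reset_index(drop=True)
    ss = compute_significance_scores(scored, padj_floor=config.padj_floor)
    ss_with_padj = ss.assign(padj=scored["padj"].to_numpy())
    thresholds = derive_ss_thresholds(
        ss_with_padj, alpha=config.alpha,
        method=config.clustering_method, seed=config.seed,
    )
    calls = call_sdegs(scored, thresholds, padj_floor=config.padj_floor)
    manifest["stages"]["sdeg"] = {
        "genes_in": int(len(de_table)),
        "genes_na_excluded": n_na,
        "genes_scored": int(len(scored)),
        "up_threshold": thresholds.up_threshold,
        "down_threshold": thresholds.down_threshold,
        "alpha": thresholds.alpha,
        "n_up": calls.n_up,
        "n_down": calls.n_down,
        "n_total_sdeg": calls.n_total_sdeg,
        "background_size": calls.background_size,
        "sdeg_fraction": calls.sdeg_fraction,
    }
    _write(ss, "significance_scores.tsv")
    _write(calls.calls, "sdeg_calls.tsv")
    bundle["thresholds"] = thresholds
    bundle["calls"] = calls

    background = (
        skio.read_gene_list(config.background)
        if config.background is not None
        else list(scored["gene_id"])
    )
    query = calls.gene_ids()

    # --- enrichment ------------------------------------------------------
    if config.gmt is not None:
        collection = skio.read_gmt(config.gmt)
        report = ora(query, collection, background, test=config.ora_test)
        _write(report[skio.ORA_REPORT_COLUMNS], "ora_report.tsv")
        cover = weighted_set_cover(report, fdr_cutoff=config.fdr_cutoff)
        if not cover.selected.empty:
            _write(cover.selected[skio.ORA_REPORT_COLUMNS], "ora_reduced.tsv")
        top = report[report["ess"] > config.ess_report_min]
        manifest["stages"]["ora"] = {
            "n_sets": len(collection),
            "n_significant": int((report["fdr"] < config.fdr_cutoff).sum()),
            "n_selected_cover": int(len(cover.selected)),
            "coverage_fraction": cover.coverage_fraction,
            "n_top_by_ess": int(len(top)),
        }
        bundle["ora"] = report
        bundle["set_cover"] = cover

        if config.run_gsea and scored["stat"].notna().all():
            ranked = scored[["gene_id", "stat"]].sort_values(
                "stat", ascending=False, kind="stable"
            ).reset_index(drop=True)
            gsea = preranked_gsea(
                ranked, collection,
                n_perm=config.gsea_n_perm, seed=config.seed,
                min_size=config.gsea_min_size,
            )
            _write(gsea, "gsea_report.tsv")
            manifest["stages"]["gsea"] = {
                "n_sets_tested": int(len(gsea)),
                "n_significant": int((gsea["fdr"] < config.fdr_cutoff).sum()),
            }
            bundle["gsea"] = gsea

        # --- matched random-list calibration ----------------------------
        if config.calibration_replicates > 0:
            spec = RandomListSpec(
                background=background,
                size=len(query),
                n_replicates=config.calibration_replicates,
                seed=config.seed,
            )
            calib = calibration_experiment(
                spec, collection, fdr_cutoff=config.fdr_cutoff, test=config.ora_test
            )
            manifest["stages"]["calibration"] = {
                "n_replicates": config.calibration_replicates,
                "n_sets": calib.n_sets_tested,
                "false_enrichment_rate": calib.false_enrichment_rate,
            }
            bundle["calibration"] = calib

    # --- meta-signature --------------------------------------------------
    if config.meta_lists:
        named = {k: skio.read_gene_list(v) for k, v in config.meta_lists.items()}
        meta = combine_meta_mission(named)
        meta = intersect_signature(meta, query)
        random_list = generate_random_lists(
            RandomListSpec(background=background, size=len(query),
                           n_replicates=1, seed=config.seed)
        )[0]
        random_overlap = len(set(meta.nonredundant) & set(random_list))
        stat, p = proportion_chisq(
            len(meta.query_overlap), meta.n_nonredundant,
            random_overlap, meta.n_nonredundant,
        )
        meta.chisq_stat, meta.chisq_p = stat, p
        skio.write_gene_list(meta.query_overlap, out_dir / "meta_signature.txt")
        manifest["outputs"].append("meta_signature.txt")
        manifest["stages"]["meta"] = {
            "source_sizes": meta.source_sizes,
            "combined_total": meta.combined_total,
            "n_nonredundant": meta.n_nonredundant,
            "nonredundant_fraction": meta.nonredundant_fraction,
            "n_query_overlap": len(meta.query_overlap),
            "overlap_proportion": meta.overlap_proportion,
            "random_overlap": random_overlap,
            "chisq_stat": stat,
            "chisq_p": p,
        }
        bundle["meta"] = meta

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    bundle["manifest"] = manifest
    return bundle
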