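"""End-to-end orchestration of the translatome analysis.

Stage order: preprocess (normalise + filters + QC) -> per-fraction
differential analysis (total RNA and the three polysome pools) ->
translation metrics (TR/TE/groups/top-n) -> clustering of the DTG
log-ratio matrix -> mRNA features of the regulated genes -> grouped
feature statistics -> optional gene-set over-representation.  Every stage
writes its table plus a JSON manifest (package version, seed, config
hash); reruns with the same config and seed are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (
    DEFAULT_COV_FAMILIES,
    DEFAULT_K_RANGE,
    cluster_log_ratio_matrix,
    summarize_clusters,
)
from .diffexpr import call_regulated, differential_by_fraction, venn_overlap
from .enrichment import ora_hypergeometric, read_gmt
from .errors import ConfigurationError, DataError
from .preprocess import cpm, filter_by_cv, filter_low_expression, qc_sample_clustering
from .seqfeatures import (
    feature_group_stats,
    feature_table,
    select_representative_transcript,
)
from .translation import (
    build_log_ratio_matrix,
    classify_translation_groups,
    polysome_monosome_ratio,
    rank_top_translated,
    translation_efficiency,
    translation_ratio,
)

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("polytome")


@dataclass(frozen=True)
class RunConfig:
    """Thresholds, grids and optional input paths for a pipeline run.

    Printed-constant defaults: DTG call at adjusted p <= 0.05 and
    |logFC| > 0.5; expression filter CPM >= 1 in every sample; variability
    filter CV < 0.75 with mean CPM > 4; TE classification at +0.5 / -0.25 /
    +-0.01.
    """

    counts_path: str | None = None
    sample_sheet_path: str | None = None
    tpm_path: str | None = None
    gtf_path: str | None = None
    fasta_path: str | None = None
    gmt_path: str | None = None
    trace_path: str | None = None
    ires_list_path: str | None = None

    alpha: float = 0.05
    lfc: float = 0.5
    te_up: float = 0.5
    te_down: float = -0.25
    te_control: float = 0.01
    cpm_threshold: float = 1.0
    cv_threshold: float = 0.75
    mean_cpm_threshold: float | None = 4.0
    top_n: int = 200
    k_range: tuple = DEFAULT_K_RANGE
    cov_families: tuple = DEFAULT_COV_FAMILIES
    seed: int = 0
    engine: str = "nussinov"
    mono_window: tuple | None = None
    poly_window: tuple | None = None

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(cfg: RunConfig, cohort):
    from . import io as pio

    if cohort is not None:
        return cohort.counts, cohort.tpm, cohort.sample_sheet, cohort.transcripts
    if cfg.counts_path is None or cfg.sample_sheet_path is None:
        raise ConfigurationError("need either an in-memory cohort or counts+sample-sheet paths")
    counts = pio.read_matrix(cfg.counts_path)
    sheet = pio.read_sample_sheet(cfg.sample_sheet_path)
    tpm = pio.read_matrix(cfg.tpm_path) if cfg.tpm_path else None
    transcripts = None
    if cfg.gtf_path and cfg.fasta_path:
        transcripts = pio.extract_transcript_records(cfg.gtf_path, cfg.fasta_path)
    return counts, tpm, sheet, transcripts


def run_pipeline(cfg: RunConfig, cohort=None, outdir: str | Path | None = None) -> dict:
    """Run every stage; return the result bundle (and write it if asked).

    ``cohort`` may be a :class:`~polytome.simulate.SyntheticCohort` (or any
    object with counts/tpm/sample_sheet/transcripts); otherwise inputs are
    read from the paths in ``cfg``.
    """
    t_start = time.perf_counter()
    counts, tpm, sheet, transcripts = _load_inputs(cfg, cohort)
    results: dict = {"config": cfg}
    stages: dict = {}

    # --- preprocess -------------------------------------------------------
    t0 = time.perf_counter()
    cpm_all = cpm(counts)
    low_mask = filter_low_expression(cpm_all, cfg.cpm_threshold)
    kept1 = low_mask.index[low_mask["keep"]]
    if len(kept1) == 0:
        raise DataError("no genes survive the low-expression (CPM) filter")
    cv_mask = filter_by_cv(
        cpm_all.loc[kept1], sheet, cfg.cv_threshold, cfg.mean_cpm_threshold
    )
    retained = cv_mask.index[cv_mask["keep"]]
    if len(retained) == 0:
        raise DataError("no genes survive the coefficient-of-variation filter")
    counts_f = counts.loc[retained]
    if tpm is None:
        raise ConfigurationError("a TPM table is required (tpm_path or cohort.tpm)")
    tpm_f = tpm.loc[retained]
    results["filters"] = pd.concat(
        [low_mask.rename(columns=lambda c: f"low_{c}"),
         cv_mask.reindex(low_mask.index).rename(columns=lambda c: f"cv_{c}")],
        axis=1,
    )
    results["qc"] = qc_sample_clustering(np.log2(tpm_f + 1.0))
    stages["preprocess"] = {"n_genes_in": int(len(counts)), "n_genes_out": int(len(retained))}
    logger.info("preprocess: %d -> %d genes (%.2fs)", len(counts), len(retained),
                time.perf_counter() - t0)

    # --- differential analysis -------------------------------------------
    t0 = time.perf_counter()
    diff = differential_by_fraction(counts_f, sheet)
    calls = {f: call_regulated(d, cfg.alpha, cfg.lfc) for f, d in diff.items()}
    dtg = set().union(*(calls[f]["up"] | calls[f]["down"] for f in ("light", "heavy")))
    deg = calls["total"]["up"] | calls["total"]["down"]
    venn = venn_overlap({"light": calls["light"]["up"], "heavy": calls["heavy"]["up"]})
    results.update(diff=diff, calls=calls, dtg=dtg, deg=deg, venn_up=venn)
    stages["diffexpr"] = {
        "n_dtg": len(dtg),
        "n_deg": len(deg),
        **{f"n_{f}_{d}": len(calls[f][d]) for f in diff for d in ("up", "down")},
    }
    logger.info("diffexpr: %d DTGs, %d DEGs (%.2fs)", len(dtg), len(deg),
                time.perf_counter() - t0)

    # --- translation metrics ---------------------------------------------
    t0 = time.perf_counter()
    tr = translation_ratio(tpm_f, sheet)
    te = translation_efficiency(tr)
    groups = classify_translation_groups(te, cfg.te_up, cfg.te_down, cfg.te_control)
    ranking = rank_top_translated(tr, n=cfg.top_n)
    results.update(tr=tr, te=te, te_groups=groups, ranking=ranking)
    stages["translation"] = {
        "n_up": int((groups == "UP").sum()),
        "n_down": int((groups == "DOWN").sum()),
        "n_control": int((groups == "CONTROL").sum()),
        "top_overlap": ranking["n_overlap"],
    }
    if cfg.trace_path and cfg.mono_window and cfg.poly_window:
        from .io import read_trace

        pos, absb = read_trace(cfg.trace_path)
        results["polysome_monosome_ratio"] = polysome_monosome_ratio(
            pos, absb, tuple(cfg.mono_window), tuple(cfg.poly_window)
        )
        stages["translation"]["polysome_monosome_ratio"] = results[
            "polysome_monosome_ratio"
        ]
    logger.info("translation metrics (%.2fs)", time.perf_counter() - t0)

    # --- clustering of the DTG log-ratio matrix ---------------------------
    t0 = time.perf_counter()
    lrm = build_log_ratio_matrix(tpm_f, sheet)
    dtg_matrix = lrm.loc[lrm.index.intersection(sorted(dtg))]
    results["log_ratio_matrix"] = lrm
    if len(dtg_matrix) >= 2 and min(cfg.k_range) <= len(dtg_matrix):
        clus = cluster_log_ratio_matrix(
            dtg_matrix, k_range=cfg.k_range, cov_families=cfg.cov_families, seed=cfg.seed
        )
        selected = clus["selected"]
        results["clustering"] = clus
        results["cluster_summary"] = summarize_clusters(selected, dtg_matrix)
        stages["clustering"] = {
            "selected_method": selected.method,
            "selected_k": selected.k,
            "silhouette": selected.silhouette,
        }
        logger.info("clustering: %s, K=%d (%.2fs)", selected.method, selected.k,
                    time.perf_counter() - t0)
    else:
        results["clustering"] = None
        stages["clustering"] = {"selected_method": None, "selected_k": 0}

    # --- mRNA features ----------------------------------------------------
    if transcripts:
        t0 = time.perf_counter()
        poly_cols = sheet.loc[
            sheet["fraction"].isin(["mono", "light", "heavy"]), "sample_id"
        ]
        poly_mean = tpm_f[list(poly_cols)].mean(axis=1)
        feature_genes = set(dtg) | set(groups.index[groups != "UNCLASSIFIED"])
        by_gene: dict[str, list] = {}
        for rec in transcripts:
            if rec.gene_id in feature_genes:
                by_gene.setdefault(rec.gene_id, []).append(rec)
        abundance = {
            rec.transcript_id: float(poly_mean.get(rec.gene_id, 0.0))
            for recs in by_gene.values()
            for rec in recs
        }
        reps = [
            select_representative_transcript(recs, abundance)
            for recs in by_gene.values()
        ]
        ires = None
        if cfg.ires_list_path:
            from .io import read_gene_list

            ires = read_gene_list(cfg.ires_list_path)
        feats = feature_table(reps, engine=cfg.engine, ires_genes=ires)
        results["features"] = feats
        stats_groups: dict[str, pd.Series] = {"te_group": groups[groups != "UNCLASSIFIED"]}
        if results.get("clustering"):
            stats_groups["cluster"] = results["clustering"]["selected"].assignments
        results["feature_stats"] = {}
        for name, g in stats_groups.items():
            labels = g.loc[g.index.intersection(feats.index)]
            if labels.nunique() >= 2 and (labels.value_counts() >= 2).all():
                results["feature_stats"][name] = feature_group_stats(feats, labels)
        stages["features"] = {"n_genes": int(len(feats))}
        logger.info("features: %d genes (%.2fs)", len(feats), time.perf_counter() - t0)

    # --- enrichment -------------------------------------------------------
    if cfg.gmt_path:
        collection = read_gmt(cfg.gmt_path)
        universe = set(retained)
        query = dtg & universe
        if query:
            results["enrichment"] = ora_hypergeometric(query, collection, universe)
            stages["enrichment"] = {"n_sets": int(len(results["enrichment"]))}

    manifest = {
        "package": "polytome",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": stages,
    }
    results["manifest"] = manifest
    logger.info("pipeline complete (%.2fs)", time.perf_counter() - t_start)
    if outdir is not None:
        _write_bundle(results, Path(outdir))
    return results


def _write_bundle(results: dict, outdir: Path) -> None:
    from .io import write_matrix

    outdir.mkdir(parents=True, exist_ok=True)
    results["filters"].to_csv(outdir / "filters.tsv", sep="\t", index_label="gene_id")
    (outdir / "qc_dendrogram.nwk").write_text(results["qc"]["newick"] + "\n")
    results["qc"]["pca"].to_csv(outdir / "qc_pca.tsv", sep="\t", index_label="sample_id")
    diff_rows = []
    for frac, d in results["diff"].items():
        d = d.reset_index(names="gene_id")
        d.insert(1, "fraction", frac)
        diff_rows.append(
            d[["gene_id", "fraction", "logFC", "ave_expr", "t", "p", "adj_p"]]
        )
    pd.concat(diff_rows, ignore_index=True).to_csv(
        outdir / "differential.tsv", sep="\t", index=False
    )
    tt = results["tr"].copy()
    tt["te"] = results["te"]
    tt["group"] = results["te_groups"]
    write_matrix(tt, outdir / "translation_table.tsv")
    write_matrix(results["log_ratio_matrix"], outdir / "log_ratio_matrix.tsv")
    if results.get("clustering"):
        sel = results["clustering"]["selected"]
        assign = sel.assignments.to_frame()
        assign["method"] = sel.method
        assign["k"] = sel.k
        write_matrix(assign, outdir / "clusters.tsv")
        results["cluster_summary"]["summary"].to_csv(
            outdir / "cluster_summary.tsv", sep="\t"
        )
        model_info = {
            "models": [
                {"method": m.method, "k": m.k, "silhouette": m.silhouette, "bic": m.bic}
                for m in results["clustering"]["models"]
            ],
            "selected": sel.method,
        }
        (outdir / "cluster_models.json").write_text(json.dumps(model_info, indent=1))
    if "features" in results:
        write_matrix(results["features"], outdir / "features.tsv")
        for name, st in results.get("feature_stats", {}).items():
            st["overall"].to_csv(outdir / f"feature_stats_{name}.tsv", sep="\t", index=False)
            st["pairwise"].to_csv(
                outdir / f"feature_stats_{name}_pairwise.tsv", sep="\t", index=False
            )
    if "enrichment" in results:
        results["enrichment"].to_csv(outdir / "enrichment.tsv", sep="\t")
    (outdir / "manifest.json").write_text(
        json.dumps(results["manifest"], indent=1, sort_keys=True) + "\n"
    )
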