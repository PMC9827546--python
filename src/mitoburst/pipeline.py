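"""End-to-end orchestration: prep -> kinetics -> enrich -> tf -> respond.

``run_pipeline`` consumes a directory of inputs in the layout produced by
:func:`mitoburst.simulate.write_outputs` (the same plain-text formats an
external dataset would arrive in), executes the stages in dependency order,
and writes every stage table plus a run manifest into the output directory.
All tables are deterministic for a fixed (inputs, config): identical reruns
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .config import AnalysisConfig, ConfigurationError
from .enrichment import group_enrichment, sliding_window_enrichment
from .kinetics import classify_reactivation, cumulative_curves, pca_dynamic_groups
from .prep import (augment_gtf_with_premrna, compute_sample_lfc,
                   compute_trajectories, filter_genes, rank_genes, select_tss)
from .proximity import (binding_level_distribution, classify_bookmarked,
                        distance_stratified_fisher, gene_bookmark_status,
                        genes_bound_fraction, metagene_profile,
                        site_count_distribution)
from .response import classify_response, de_test, response_group_summary

logger = logging.getLogger("mitoburst")

INPUT_FILES = {
    "expression": "expression_tpm.tsv",
    "samples": "samples.tsv",
    "gtf": "annotation.gtf",
    "evidence": "tss_evidence.tsv",
    "curated": "curated_ids.txt",
    "peaks_interphase": "peaks_interphase.bed",
    "peaks_mitotic": "peaks_mitotic.bed",
    "coverage": "coverage.bedgraph",
    "gene_sets": "gene_sets.gmt",
    "library_size": "library_size.txt",
}


def default_synthetic_config(n_genes: int = 2_000) -> AnalysisConfig:
    """Analysis config scaled to the synthetic study size.

    The PCA loading groups shrink from 1,000 genes (full-data scale) to
    one-tenth of the simulated gene count so the t/b groups stay disjoint
    halves of a much smaller universe; the ranked-list window scales the
    same way (a 500-gene window only fits a ranking of thousands).
    """
    window = min(500, max(20, n_genes // 5))
    return AnalysisConfig(loading_group_size=max(10, n_genes // 10),
                          enrich_window_genes=window,
                          enrich_step_genes=max(5, window // 10))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(indir: str | Path, outdir: str | Path,
                 cfg: AnalysisConfig | None = None,
                 de_method: str = "moderated",
                 import_de: str | Path | None = None) -> dict:
    """Execute all stages over an input directory; returns the manifest."""
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: indir / v for k, v in INPUT_FILES.items()}
    missing = [str(p) for p in paths.values() if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing pipeline inputs: {missing}")

    manifest: dict = {"inputs": {k: _digest(p) for k, p in sorted(paths.items())},
                      "stages": {}}

    expr = mio.read_expression(paths["expression"])
    sheet = mio.read_sample_sheet(paths["samples"])
    curated = {line.strip() for line in paths["curated"].read_text().splitlines() if line.strip()}
    if cfg is None:
        cfg = default_synthetic_config(len(expr))
    manifest["config"] = {k: (list(v) if isinstance(v, tuple) else v)
                          for k, v in vars(cfg).items()}

    # ---- prep ------------------------------------------------------------
    stage = "prep"
    try:
        genes = mio.read_gtf(paths["gtf"])
        evidence = mio.read_table(paths["evidence"])
        augmented = augment_gtf_with_premrna(genes)
        mio.write_gtf(augmented, outdir / "annotation_premrna.gtf")
        tss = select_tss(genes, evidence)
        mio.write_table(tss, outdir / "tss_selected.tsv")

        kept = filter_genes(expr, sheet, cfg, curated)
        expr_f = expr.loc[kept]
        conditions = [c for c in ("untreated", "IAA") if c in set(sheet["condition"])]
        trajs = {c: compute_trajectories(expr_f, sheet, cfg, condition=c) for c in conditions}
        ranked = rank_genes(trajs["untreated"])
        for c, tr in trajs.items():
            mio.write_table(tr.table.reset_index().rename(columns={"index": "gene_id"}),
                            outdir / f"trajectories_{c}.tsv")
            mio.write_table(tr.zscores.reset_index().rename(columns={"index": "gene_id"}),
                            outdir / f"zscores_{c}.tsv")
        mio.write_table(pd.DataFrame({"rank": np.arange(1, len(ranked) + 1), "gene_id": ranked}),
                        outdir / "ranked_genes.tsv")
        manifest["stages"][stage] = {"n_genes_in": len(expr), "n_genes_filtered": len(kept),
                                     "n_tss": len(tss)}
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ---- kinetics --------------------------------------------------------
    stage = "kinetics"
    try:
        classes = classify_reactivation(trajs["untreated"], cfg)
        mio.write_table(classes, outdir / "reactivation_classes.tsv")
        curves = cumulative_curves(trajs["untreated"], classes)
        mio.write_table(curves, outdir / "cumulative_curves.tsv")
        sample_lfc, _ = compute_sample_lfc(expr_f, sheet, cfg, condition="untreated")
        pca, groups = pca_dynamic_groups(sample_lfc, cfg)
        mio.write_table(pca.scores.reset_index(names="sample_id"), outdir / "pca_scores.tsv")
        mio.write_table(pca.loadings.reset_index(names="gene_id"), outdir / "pca_loadings.tsv")
        mio.write_table(pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(pca.variance_fraction))],
                                      "variance_fraction": pca.variance_fraction}),
                        outdir / "pca_variance.tsv")
        mio.write_table(pd.DataFrame([(g, gid) for g in sorted(groups) for gid in groups[g]],
                                     columns=["group", "gene_id"]),
                        outdir / "pca_groups.tsv")
        manifest["stages"][stage] = {
            "class_counts": classes["class"].value_counts().to_dict(),
            "pc_variance": [round(float(v), 6) for v in pca.variance_fraction]}
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ---- enrich ----------------------------------------------------------
    stage = "enrich"
    try:
        gene_sets = mio.read_gmt(paths["gene_sets"])
        track = sliding_window_enrichment(ranked, gene_sets, cfg)
        mio.write_table(track, outdir / "window_enrichment.tsv")
        group_tables = []
        for gname, members in sorted(groups.items()):
            tab = group_enrichment(members, kept, gene_sets)
            tab.insert(0, "group", gname)
            group_tables.append(tab)
        mio.write_table(pd.concat(group_tables, ignore_index=True),
                        outdir / "group_enrichment.tsv")
        manifest["stages"][stage] = {"n_window_rows": len(track)}
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ---- tf --------------------------------------------------------------
    stage = "tf"
    try:
        inter = mio.read_peaks(paths["peaks_interphase"], "interphase")
        mito = mio.read_peaks(paths["peaks_mitotic"], "mitotic")
        labels = classify_bookmarked(inter, mito)
        mio.write_table(labels, outdir / "bookmark_labels.tsv")
        tss_f = tss[tss["gene_id"].isin(kept)].reset_index(drop=True)
        class_groups = classes.rename(columns={"class": "class"})[["gene_id", "class"]]
        mio.write_table(genes_bound_fraction(class_groups, inter.df, tss_f, cfg),
                        outdir / "bound_fraction_by_class.tsv")
        mio.write_table(gene_bookmark_status(inter, labels, tss_f, cfg),
                        outdir / "gene_bookmark_status.tsv")
        mio.write_table(site_count_distribution(class_groups, inter.df, tss_f, cfg),
                        outdir / "site_count_distribution.tsv")
        mio.write_table(binding_level_distribution(
            class_groups, {"interphase": inter, "mitotic": mito}, tss_f, cfg),
            outdir / "binding_levels.tsv")
        mio.write_table(distance_stratified_fisher(class_groups, inter, labels, tss_f, cfg),
                        outdir / "distance_fisher_reactivation.tsv")
        library_size = float(paths["library_size"].read_text().strip())
        coverage = mio.read_bedgraph(paths["coverage"])
        mio.write_table(metagene_profile(coverage, tss_f, library_size, cfg),
                        outdir / "metagene_profile.tsv")
        manifest["stages"][stage] = {
            "n_interphase_peaks": len(inter), "n_mitotic_peaks": len(mito),
            "n_book": int((labels["label"] == "Book").sum())}
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ---- respond ---------------------------------------------------------
    stage = "respond"
    if "IAA" in set(sheet["condition"]):
        try:
            if import_de is not None:
                de = mio.read_table(import_de, dtype={"contrast": str})
            else:
                de = de_test(expr_f, sheet, cfg, method=de_method)
            mio.write_table(de, outdir / "de_results.tsv")
            rclasses = classify_response(de, cfg)
            mio.write_table(rclasses, outdir / "response_classes.tsv")
            zs = {c: trajs[c].zscores for c in trajs}
            mio.write_table(response_group_summary(rclasses, zs),
                            outdir / "response_summaries.tsv")
            concordant = rclasses[rclasses["timing"] != "discordant"]
            if len(concordant):
                mapping = {r.gene_id: f"{r.timing}_{r.direction}"
                           for r in concordant.itertuples()}
                resp_groups = pd.DataFrame({
                    "gene_id": kept,
                    "class": [mapping.get(g, "no_response") for g in kept]})
                mio.write_table(
                    distance_stratified_fisher(resp_groups, inter, labels, tss_f, cfg),
                    outdir / "distance_fisher_response.tsv")
            manifest["stages"][stage] = {
                "n_responders": int(len(concordant)),
                "n_discordant": int((rclasses["timing"] == "discordant").sum()),
                "response_counts": (concordant.assign(
                    cls=concordant["timing"] + "_" + concordant["direction"])
                    ["cls"].value_counts().to_dict()) if len(concordant) else {}}
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    else:
        manifest["stages"][stage] = {"skipped": "no IAA arm in sample sheet"}

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
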