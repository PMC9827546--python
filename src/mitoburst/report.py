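"""Static figure generation from pipeline stage tables.

Each panel is rendered from the stage TSV it mirrors and the exact data
behind the panel is copied next to the image as ``<panel>_data.tsv``, so
every figure can be re-plotted from text alone.  Missing stage outputs
skip their panel with a notice instead of failing the report.
"""

from __future__ import annotations

import logging
import shutil
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import io as mio

logger = logging.getLogger("mitoburst")


def _panel(outdir: Path, name: str, source: Path) -> bool:
    if not source.exists():
        logger.warning("panel %s skipped: %s missing", name, source.name)
        return False
    shutil.copy(source, outdir / f"{name}_data.tsv")
    return True


def make_report(run_dir: str | Path, fig_dir: str | Path | None = None) -> list[str]:
    """Render all available panels; returns the list of written panel names."""
    run_dir = Path(run_dir)
    fig_dir = Path(fig_dir) if fig_dir else run_dir / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    # ranked fold-change heatmap
    traj_p, rank_p = run_dir / "trajectories_untreated.tsv", run_dir / "ranked_genes.tsv"
    if traj_p.exists() and rank_p.exists():
        traj = mio.read_table(traj_p, index_col="gene_id")
        ranked = mio.read_table(rank_p)["gene_id"].tolist()
        cols = ["log2fc_async"] + [c for c in traj.columns if c.startswith("lfc_")]
        mat = traj.loc[[g for g in ranked if g in traj.index], cols]
        fig, ax = plt.subplots(figsize=(4, 6))
        if len(mat):
            lim = np.nanpercentile(np.abs(mat.to_numpy()), 98) or 1.0
            ax.imshow(mat.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-lim, vmax=lim)
        ax.set_xticks(range(len(cols)), [c.replace("lfc_", "") for c in cols], rotation=90)
        ax.set_ylabel("genes (ranked by mean 20-90 min fold change)")
        ax.set_title("log2 fold change to mitosis")
        fig.savefig(fig_dir / "heatmap_ranked_lfc.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        _panel(fig_dir, "heatmap_ranked_lfc", traj_p)
        written.append("heatmap_ranked_lfc")
    else:
        logger.warning("panel heatmap_ranked_lfc skipped: stage output missing")

    # cumulative curves
    p = run_dir / "cumulative_curves.tsv"
    if p.exists():
        curves = mio.read_table(p)
        fig, ax = plt.subplots()
        ax.plot(curves["time_min"], curves["pct_max_reached"], "-o", label="maximum reached")
        ax.plot(curves["time_min"], curves["pct_async_reached"], "-s", label="asynchronous level reached")
        ax.set_xlabel("minutes after release"); ax.set_ylabel("% of genes")
        ax.set_ylim(0, 100); ax.legend()
        fig.savefig(fig_dir / "cumulative_curves.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        _panel(fig_dir, "cumulative_curves", p)
        written.append("cumulative_curves")

    # PCA biplot
    p = run_dir / "pca_scores.tsv"
    if p.exists():
        scores = mio.read_table(p)
        fig, ax = plt.subplots()
        ax.scatter(scores["PC1"], scores.get("PC2", 0.0))
        for _, r in scores.iterrows():
            ax.annotate(str(r["sample_id"]), (r["PC1"], r.get("PC2", 0.0)), fontsize=6)
        ax.set_xlabel("PC1"); ax.set_ylabel("PC2")
        fig.savefig(fig_dir / "pca_biplot.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        _panel(fig_dir, "pca_biplot", p)
        written.append("pca_biplot")

    # sliding-window enrichment tracks
    p = run_dir / "window_enrichment.tsv"
    if p.exists():
        track = mio.read_table(p)
        fig, ax = plt.subplots()
        for term, sub in track.groupby("term"):
            ax.plot(sub["start_rank"], sub["neg_log10_fdr"].replace(np.inf, np.nan), label=term)
        ax.set_xlabel("window start rank"); ax.set_ylabel("-log10 FDR")
        ax.legend(fontsize=6)
        fig.savefig(fig_dir / "window_enrichment.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        _panel(fig_dir, "window_enrichment", p)
        written.append("window_enrichment")

    # distance-stratified Fisher tracks
    for stem in ("distance_fisher_reactivation", "distance_fisher_response"):
        p = run_dir / f"{stem}.tsv"
        if not p.exists():
            continue
        tab = mio.read_table(p)
        fig, ax = plt.subplots()
        for (cls, lab), sub in tab.groupby(["class", "label"]):
            ax.plot(np.log10(sub["distance_kb"]), sub["neg_log10_p"],
                    "-o" if lab == "Book" else "--s", label=f"{cls}/{lab}", alpha=0.7)
        ax.set_xlabel("log10 distance (kb)"); ax.set_ylabel("-log10 p")
        ax.legend(fontsize=5)
        fig.savefig(fig_dir / f"{stem}.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        _panel(fig_dir, stem, p)
        written.append(stem)

    # metagene profile
    p = run_dir / "metagene_profile.tsv"
    if p.exists():
        prof = mio.read_table(p)
        fig, ax = plt.subplots()
        ax.plot(prof["offset_bp"], prof["rpm"])
        ax.set_xlabel("offset from TSS (bp)"); ax.set_ylabel("RPM")
        fig.savefig(fig_dir / "metagene_profile.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        _panel(fig_dir, "metagene_profile", p)
        written.append("metagene_profile")

    # response-class boxplots (medians with quartile band)
    p = run_dir / "response_summaries.tsv"
    if p.exists():
        summ = mio.read_table(p)
        release = summ[summ["sample"].astype(str).str.startswith("t")]
        if len(release):
            fig, ax = plt.subplots()
            for (cls, arm), sub in release.groupby(["class", "arm"]):
                t = sub["sample"].str.lstrip("t").astype(float)
                ax.plot(t, sub["median"], "-" if arm == "untreated" else "--",
                        label=f"{cls} ({arm})", alpha=0.7)
            ax.set_xlabel("minutes after release"); ax.set_ylabel("median z-score")
            ax.legend(fontsize=5)
            fig.savefig(fig_dir / "response_classes.png", dpi=120, bbox_inches="tight")
            plt.close(fig)
        _panel(fig_dir, "response_classes", p)
        written.append("response_classes")

    if not written:
        logger.warning("no stage outputs found; report contains placeholder panels only")
    return written
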