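#!/usr/bin/env python
"""Reactivation timing classes, cumulative curves, PCA groups, enrichment.

Classifies every filtered gene by when its trajectory reaches asynchronous
levels (G1_high / t40 / t50 / t60 / t90 / late), derives the cumulative
reactivation curves, extracts PCA loading groups from per-sample fold
changes, and scans planted gene sets along the ranking with a
sliding-window Fisher test.
"""

from pathlib import Path

import pandas as pd

import mitoburst as mb
from mitoburst import io as mio
from mitoburst.enrichment import group_enrichment, sliding_window_enrichment
from mitoburst.kinetics import classify_reactivation, cumulative_curves, pca_dynamic_groups
from mitoburst.pipeline import default_synthetic_config
from mitoburst.prep import TrajectorySet, compute_sample_lfc

ROOT = Path(__file__).resolve().parents[1] / "results"


def load_traj(path: Path) -> TrajectorySet:
    table = mio.read_table(path, index_col="gene_id")
    tps = tuple(sorted(int(c.split("_")[1]) for c in table.columns if c.startswith("lfc_")))
    return TrajectorySet(timepoints=tps, table=table, zscores=pd.DataFrame(index=table.index))


def main() -> None:
    indir, out = ROOT / "synthetic", ROOT / "analysis"
    traj = load_traj(out / "trajectories_untreated.tsv")
    cfg = default_synthetic_config(2_000)

    classes = classify_reactivation(traj, cfg)
    mio.write_table(classes, out / "reactivation_classes.tsv")
    counts = classes["class"].value_counts().to_dict()
    print("reactivation classes:", counts)

    curves = cumulative_curves(traj, classes)
    mio.write_table(curves, out / "cumulative_curves.tsv")
    print(f"maximum-reached plateau: {curves['pct_max_reached'].iloc[-1]:.1f}% "
          f"(the rest peak in asynchronous cells)")

    expr = mio.read_expression(indir / "expression_tpm.tsv")
    sheet = mio.read_sample_sheet(indir / "samples.tsv")
    lfc, _ = compute_sample_lfc(expr.loc[traj.table.index], sheet, cfg)
    pca, groups = pca_dynamic_groups(lfc, cfg)
    mio.write_table(pd.DataFrame([(g, gid) for g in sorted(groups) for gid in groups[g]],
                                 columns=["group", "gene_id"]), out / "pca_groups.tsv")
    print(f"PC1/PC2 variance: {100*pca.variance_fraction[0]:.1f}% / "
          f"{100*pca.variance_fraction[1]:.1f}%")

    gene_sets = mio.read_gmt(indir / "gene_sets.gmt")
    ranked = mio.read_table(out / "ranked_genes.tsv")["gene_id"].tolist()
    track = sliding_window_enrichment(ranked, gene_sets, cfg)
    mio.write_table(track, out / "window_enrichment.tsv")
    best = track.loc[track["neg_log10_fdr"].idxmax()]
    print(f"strongest window enrichment: {best['term']} at ranks "
          f"{best['start_rank']}-{best['end_rank']} (-log10 FDR {best['neg_log10_fdr']:.1f})")

    tables = []
    for g in sorted(groups):
        t = group_enrichment(groups[g], list(traj.table.index), gene_sets)
        t.insert(0, "group", g)
        tables.append(t)
    mio.write_table(pd.concat(tables, ignore_index=True), out / "group_enrichment.tsv")


if __name__ == "__main__":
    main()
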