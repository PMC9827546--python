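"""Peak-to-gene integration: bookmarking labels, TSS-window statistics,
distance-stratified Fisher enrichment, and metagene coverage profiles.

Coordinates are 0-based half-open throughout.  "Distance" from a TSS to a
peak is the gap to the nearest peak edge, 0 when the TSS falls inside the
peak.  Window association uses any >=1 bp interval overlap with the
TSS-centred window.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .enrichment import bh_fdr, fisher_exact
from .io import PeakSet

logger = logging.getLogger("mitoburst")


# ---------------------------------------------------------------------------
# interval machinery (sorted-array fast paths; brute force lives in tests)
# ---------------------------------------------------------------------------

def _overlap_counts(tss_win: pd.DataFrame, peaks: pd.DataFrame) -> np.ndarray:
    """Number of peak intervals overlapping each query window (>=1 bp)."""
    counts = np.zeros(len(tss_win), dtype=int)
    for chrom, qsub in tss_win.groupby("chrom"):
        psub = peaks[peaks["chrom"] == chrom]
        if psub.empty:
            continue
        starts = np.sort(psub["start"].to_numpy())
        ends = np.sort(psub["end"].to_numpy())
        # overlap iff peak.start < win.end and peak.end > win.start
        n_start_before_end = np.searchsorted(starts, qsub["end"].to_numpy(), side="left")
        n_end_before_start = np.searchsorted(ends, qsub["start"].to_numpy(), side="right")
        counts[qsub.index.to_numpy()] = n_start_before_end - n_end_before_start
    return counts


def nearest_peak_distance(tss: pd.DataFrame, peaks: pd.DataFrame) -> np.ndarray:
    """Distance from each TSS to the closest edge of the nearest peak.

    0 if the TSS lies inside a peak; inf if the chromosome has no peak.
    """
    dist = np.full(len(tss), np.inf)
    tss = tss.reset_index(drop=True)
    for chrom, qsub in tss.groupby("chrom"):
        psub = peaks[peaks["chrom"] == chrom]
        if psub.empty:
            continue
        order = np.argsort(psub["start"].to_numpy(), kind="mergesort")
        starts = psub["start"].to_numpy()[order]
        ends = psub["end"].to_numpy()[order]
        ends_cummax = np.maximum.accumulate(ends)
        pos = qsub["pos"].to_numpy()
        out = np.full(len(pos), np.inf)
        for i, t in enumerate(pos):
            j = np.searchsorted(starts, t, side="right")  # peaks with start <= t
            best = np.inf
            if j < len(starts):
                best = starts[j] - t  # nearest peak starting after t
            if j > 0:
                # among peaks starting at or before t: inside if any end > t
                if ends_cummax[j - 1] > t:
                    best = 0.0
                else:
                    # all such peaks end at or before t; nearest trailing edge
                    best = min(best, t - ends_cummax[j - 1] + 1)
            out[i] = best
        dist[qsub.index.to_numpy()] = out
    return dist


def _tss_windows(tss: pd.DataFrame, window_bp: int) -> pd.DataFrame:
    half = window_bp // 2
    win = tss.reset_index(drop=True).copy()
    win["start"] = np.maximum(win["pos"] - half, 0)
    win["end"] = win["pos"] + half
    return win


# ---------------------------------------------------------------------------
# bookmarking
# ---------------------------------------------------------------------------

def classify_bookmarked(interphase: PeakSet, mitotic: PeakSet) -> pd.DataFrame:
    """Label every interphase peak Book (overlaps >=1 mitotic peak by >=1 bp)
    or Lost.  Mitotic peaks on chromosomes absent from the interphase set
    indicate mismatched coordinate spaces and raise."""
    inter_chroms = set(interphase.df["chrom"])
    unmatched = sorted(set(mitotic.df["chrom"]) - inter_chroms)
    if unmatched:
        raise ValueError(f"mitotic peaks on chromosomes absent from the "
                         f"interphase set: {unmatched}")
    queries = interphase.df.reset_index(drop=True)[["chrom", "start", "end"]]
    counts = _overlap_counts(queries, mitotic.df)
    return pd.DataFrame({
        "peak_id": interphase.df["peak_id"].to_numpy(),
        "label": np.where(counts > 0, "Book", "Lost"),
    })


def _split_labelled(interphase: PeakSet, labels: pd.DataFrame) -> dict[str, pd.DataFrame]:
    merged = interphase.df.merge(labels, on="peak_id", how="left")
    return {lab: merged[merged["label"] == lab].reset_index(drop=True)
            for lab in ("Book", "Lost")}


# ---------------------------------------------------------------------------
# per-group statistics
# ---------------------------------------------------------------------------

def genes_bound_fraction(groups: pd.DataFrame, peaks: pd.DataFrame,
                         tss: pd.DataFrame, cfg: AnalysisConfig,
                         class_col: str = "class") -> pd.DataFrame:
    """Percent of genes per group with >=1 peak in the TSS-centred window."""
    merged = groups.merge(tss, on="gene_id", how="inner")
    win = _tss_windows(merged, cfg.tss_window_bp)
    bound = _overlap_counts(win, peaks) > 0
    merged = merged.assign(bound=bound)
    rows = []
    for cls, sub in merged.groupby(class_col, sort=True):
        rows.append({class_col: cls, "n_genes": len(sub),
                     "pct_bound": 100.0 * sub["bound"].mean() if len(sub) else 0.0})
    return pd.DataFrame(rows)


def gene_bookmark_status(interphase: PeakSet, labels: pd.DataFrame,
                         tss: pd.DataFrame, cfg: AnalysisConfig) -> pd.DataFrame:
    """Gene-level dichotomy: ``bookmarked`` = >=1 Book peak in the window;
    ``lost`` = >=1 interphase peak but no Book peak; else ``unbound``."""
    by_label = _split_labelled(interphase, labels)
    win = _tss_windows(tss, cfg.tss_window_bp)
    n_book = _overlap_counts(win, by_label["Book"])
    n_any = _overlap_counts(win, interphase.df)
    status = np.where(n_book > 0, "bookmarked", np.where(n_any > 0, "lost", "unbound"))
    return pd.DataFrame({"gene_id": win["gene_id"], "status": status,
                         "n_book": n_book, "n_interphase": n_any})


def site_count_distribution(groups: pd.DataFrame, peaks: pd.DataFrame,
                            tss: pd.DataFrame, cfg: AnalysisConfig,
                            class_col: str = "class") -> pd.DataFrame:
    """Per group: proportion of genes with each window peak count, rescaled
    to the group's maximal proportion."""
    merged = groups.merge(tss, on="gene_id", how="inner")
    win = _tss_windows(merged, cfg.tss_window_bp)
    merged = merged.assign(count=_overlap_counts(win, peaks))
    rows = []
    for cls, sub in merged.groupby(class_col, sort=True):
        freq = sub["count"].value_counts(normalize=True).sort_index()
        peak_prop = freq.max() if len(freq) else 1.0
        for count, prop in freq.items():
            rows.append({class_col: cls, "count": int(count), "proportion": prop,
                         "scaled": prop / peak_prop})
    return pd.DataFrame(rows)


def binding_level_distribution(groups: pd.DataFrame,
                               peaks_by_condition: Mapping[str, PeakSet],
                               tss: pd.DataFrame, cfg: AnalysisConfig,
                               class_col: str = "class") -> pd.DataFrame:
    """Multiset of RPM heights of window-overlapping peaks per group and
    condition (a peak near several genes contributes once per gene)."""
    merged = groups.merge(tss, on="gene_id", how="inner")
    win = _tss_windows(merged, cfg.tss_window_bp)
    rows = []
    for cond, pset in sorted(peaks_by_condition.items()):
        pk = pset.df
        for chrom, qsub in win.groupby("chrom"):
            psub = pk[pk["chrom"] == chrom]
            if psub.empty:
                continue
            ps = psub["start"].to_numpy()
            pe = psub["end"].to_numpy()
            ph = psub["height"].to_numpy()
            for _, q in qsub.iterrows():
                hit = (ps < q["end"]) & (pe > q["start"])
                for h in ph[hit]:
                    rows.append({class_col: merged.loc[q.name, class_col],
                                 "condition": cond, "height": float(h)})
    return pd.DataFrame(rows, columns=[class_col, "condition", "height"])


def distance_stratified_fisher(groups: pd.DataFrame, interphase: PeakSet,
                               labels: pd.DataFrame, tss: pd.DataFrame,
                               cfg: AnalysisConfig,
                               class_col: str = "class") -> pd.DataFrame:
    """One-sided Fisher enrichment of each gene group among genes whose
    nearest Book (or Lost) peak lies within each distance stratum.

    The universe is every gene in ``groups``; the 2x2 at distance d is
    [group & within-d, group & beyond-d; rest & within-d, rest & beyond-d].
    """
    by_label = _split_labelled(interphase, labels)
    merged = groups.merge(tss, on="gene_id", how="inner").reset_index(drop=True)
    rows = []
    for lab in ("Book", "Lost"):
        dist = nearest_peak_distance(merged, by_label[lab])
        for cls in sorted(merged[class_col].unique()):
            in_group = (merged[class_col] == cls).to_numpy()
            if in_group.sum() == 0:
                logger.warning("empty group %s skipped", cls)
                continue
            for d_kb in cfg.distance_grid_kb:
                within = dist <= d_kb * 1_000
                a = int((in_group & within).sum())
                b = int((in_group & ~within).sum())
                c = int((~in_group & within).sum())
                d = int((~in_group & ~within).sum())
                res = fisher_exact(a, b, c, d, sided="greater")
                rows.append({class_col: cls, "label": lab, "distance_kb": d_kb,
                             "group_within": a, "universe_within": a + c,
                             "odds_ratio": res.odds_ratio, "p": res.p,
                             "log10_p": res.log10_p, "neg_log10_p": -res.log10_p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------

def metagene_profile(coverage: pd.DataFrame, tss: pd.DataFrame,
                     library_size: float, cfg: AnalysisConfig,
                     chrom_sizes: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Average strand-oriented coverage around TSSs, binned and RPM-scaled.

    Each gene contributes the per-bin sum of coverage over
    ``[TSS - span/2, TSS + span/2)``; minus-strand windows are flipped so
    upstream is always on the left.  The mean over genes is scaled by
    1e6 / library_size.  Genes whose window leaves the chromosome bounds
    are dropped (count logged).
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    span, binw = cfg.metagene_span_bp, cfg.metagene_bin_bp
    half = span // 2
    nbins = span // binw
    if chrom_sizes is None:
        chrom_sizes = coverage.groupby("chrom")["end"].max().to_dict()

    profiles = []
    dropped = 0
    for chrom, qsub in tss.groupby("chrom"):
        csize = int(chrom_sizes.get(chrom, 0))
        base = np.zeros(csize, dtype=float)
        csub = coverage[coverage["chrom"] == chrom]
        for s, e, v in zip(csub["start"], csub["end"], csub["value"]):
            base[max(0, int(s)):min(csize, int(e))] += v
        for _, row in qsub.iterrows():
            lo, hi = int(row["pos"]) - half, int(row["pos"]) + half
            if lo < 0 or hi > csize:
                dropped += 1
                continue
            bins = base[lo:hi].reshape(nbins, binw).sum(axis=1)
            if row["strand"] == "-":
                bins = bins[::-1]
            profiles.append(bins)
    if dropped:
        logger.info("metagene_profile: %d genes dropped (window beyond chromosome bounds)", dropped)
    offsets = np.arange(nbins) * binw - half + binw // 2
    if not profiles:
        return pd.DataFrame({"offset_bp": offsets, "rpm": np.zeros(nbins)})
    mean_prof = np.mean(profiles, axis=0) * 1e6 / library_size
    return pd.DataFrame({"offset_bp": offsets, "rpm": mean_prof})
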