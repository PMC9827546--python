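"""Reactivation-timing classification, cumulative curves, PCA gene groups.

A gene's reactivation time is the earliest post-release timepoint at which
its fold change to mitosis reaches (>=) the level measured in asynchronous
cells.  Genes below their mitotic level in asynchronous populations form a
separate early-G1 class (``G1_high``) that takes precedence, since such
genes trivially "reach" asynchronous levels immediately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .prep import TrajectorySet

logger = logging.getLogger("mitoburst")

REACTIVATION_CLASSES = ("G1_high", "t40", "t50", "t60", "t90", "late", "unclassifiable")


def time_to_async(lfc: pd.Series, log2fc_async: float,
                  timepoints: tuple[int, ...]) -> float | None:
    """Earliest release minute where the trajectory reaches the asynchronous
    level (>=); None if never."""
    for t in timepoints:
        v = lfc.get(f"lfc_{t}", np.nan)
        if np.isfinite(v) and v >= log2fc_async:
            return float(t)
    return None


def classify_reactivation(traj: TrajectorySet, cfg: AnalysisConfig) -> pd.DataFrame:
    """Assign every gene exactly one reactivation class.

    Precedence: (1) G1_high iff the asynchronous fold change is negative;
    else (2) by first-reach time: <=40 -> t40, 50 -> t50, 60 -> t60,
    90 -> t90, 120 or never -> late.  Genes with incomplete trajectories go
    to an explicit ``unclassifiable`` bucket, never silently dropped.
    ``max_at`` labels where the trajectory maximum occurs, including the
    asynchronous anchor (the mitotic anchor, identically 0, is excluded).
    """
    rows = []
    for gid, row in traj.table.iterrows():
        lfc_vals = {t: row.get(f"lfc_{t}", np.nan) for t in traj.timepoints}
        complete = np.isfinite(row["log2fc_async"]) and all(np.isfinite(v) for v in lfc_vals.values())
        if not complete:
            rows.append({"gene_id": gid, "class": "unclassifiable",
                         "first_reach_min": np.nan, "max_at": "", "rule": "incomplete trajectory"})
            continue
        candidates = [("asynchronous", row["log2fc_async"])] + \
                     [(f"t{t}", lfc_vals[t]) for t in traj.timepoints]
        max_at = max(candidates, key=lambda kv: kv[1])[0]
        reach = time_to_async(row, row["log2fc_async"], traj.timepoints)
        if row["log2fc_async"] < 0:
            cls, rule = "G1_high", "log2fc_async < 0"
        elif reach is not None and reach <= 40:
            cls, rule = "t40", f"first reach at {reach:.0f} min"
        elif reach in (50.0, 60.0, 90.0):
            cls, rule = f"t{reach:.0f}", f"first reach at {reach:.0f} min"
        else:
            cls, rule = "late", ("first reach at 120 min" if reach == 120.0 else "never reached")
        rows.append({"gene_id": gid, "class": cls, "first_reach_min": np.nan if reach is None else reach,
                     "max_at": max_at, "rule": rule})
    return pd.DataFrame(rows)


def cumulative_curves(traj: TrajectorySet, classes: pd.DataFrame) -> pd.DataFrame:
    """Percentage of genes (a) past their trajectory maximum and (b) at or
    above asynchronous levels, by release minute.

    Genes whose maximum sits at the asynchronous anchor never enter the
    maximum curve, so its plateau equals 100 minus their percentage.
    """
    usable = classes[classes["class"] != "unclassifiable"]
    n = len(usable)
    max_minute = usable["max_at"].map(
        lambda lab: np.inf if lab == "asynchronous" else float(lab[1:]))
    rows = []
    for t in traj.timepoints:
        rows.append({"time_min": t,
                     "pct_max_reached": 100.0 * (max_minute <= t).sum() / n if n else 0.0,
                     "pct_async_reached": 100.0 * (usable["first_reach_min"] <= t).sum() / n if n else 0.0})
    return pd.DataFrame(rows)


@dataclass
class PcaResult:
    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # genes x components
    variance_fraction: np.ndarray   # per component, non-increasing


def pca_dynamic_groups(sample_lfc: pd.DataFrame, cfg: AnalysisConfig,
                       n_components: int = 2) -> tuple[PcaResult, dict[str, list[str]]]:
    """Exact SVD on per-gene-centred per-sample fold changes.

    Rows are samples, columns genes.  The sign of each component is fixed so
    the score of the last sample row is non-negative, making results stable
    across linear-algebra backends.  For each of the first two components
    the genes with largest and smallest loadings form the t/b groups
    (PC1t, PC1b, PC2t, PC2b), each of size ``cfg.loading_group_size``.
    """
    if sample_lfc.shape[0] < 3:
        raise ValueError("PCA needs at least 3 samples")
    k = cfg.loading_group_size
    n_genes = sample_lfc.shape[1]
    if k > n_genes / 2:
        raise ValueError(f"loading_group_size {k} exceeds half the gene count {n_genes}")

    centred = sample_lfc - sample_lfc.mean(axis=0)
    u, s, vt = np.linalg.svd(centred.to_numpy(), full_matrices=False)
    total = float((s ** 2).sum())
    var_frac = (s ** 2) / total if total > 0 else np.zeros_like(s)
    scores = u * s
    # sign convention: last sample scores >= 0
    for j in range(len(s)):
        if scores[-1, j] < 0:
            scores[:, j] *= -1
            vt[j, :] *= -1
    ncomp = min(n_components, len(s))
    result = PcaResult(
        scores=pd.DataFrame(scores[:, :ncomp], index=sample_lfc.index,
                            columns=[f"PC{i+1}" for i in range(ncomp)]),
        loadings=pd.DataFrame(vt[:ncomp].T, index=sample_lfc.columns,
                              columns=[f"PC{i+1}" for i in range(ncomp)]),
        variance_fraction=var_frac[:ncomp],
    )
    groups: dict[str, list[str]] = {}
    for i in range(min(2, ncomp)):
        load = result.loadings[f"PC{i+1}"]
        order = load.sort_values(kind="mergesort")
        groups[f"PC{i+1}b"] = sorted(order.index[:k])
        groups[f"PC{i+1}t"] = sorted(order.index[-k:])
    return result, groups
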