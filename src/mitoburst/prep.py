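"""From TPM matrices to filtered, replicate-averaged fold-change trajectories.

Also houses the two annotation-side rules the quantification depends on:
adding a single-exon pre-mRNA isoform spanning each gene's longest
transcript (so intronic signal is captured as a proxy for ongoing
transcription), and choosing one primary TSS per gene from chromatin
evidence (RNAPII, H3K4me3, DNaseI).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig, ConfigurationError
from .io import Gene, Transcript

logger = logging.getLogger("mitoburst")

PREMRNA_SUFFIX = ".premrna"


# ---------------------------------------------------------------------------
# annotation rules
# ---------------------------------------------------------------------------

def augment_gtf_with_premrna(genes: list[Gene], union: bool = False) -> list[Gene]:
    """Add one single-exon pre-mRNA transcript per gene.

    The new transcript spans the gene's longest-span existing transcript
    (or, with ``union=True``, the union of all transcript spans).  Original
    records are left untouched; transcripts without exons are warned about
    and do not contribute a pre-mRNA isoform.
    """
    out: list[Gene] = []
    for g in genes:
        g2 = copy.deepcopy(g)
        with_exons = [t for t in g2.transcripts if t.exons]
        for t in g2.transcripts:
            if not t.exons:
                logger.warning("transcript %s of gene %s has no exons; skipped",
                               t.transcript_id, g.gene_id)
        if not with_exons:
            logger.warning("gene %s has no exon-bearing transcript; no pre-mRNA added", g.gene_id)
            out.append(g2)
            continue
        if union:
            start = min(t.start for t in with_exons)
            end = max(t.end for t in with_exons)
        else:
            # longest span wins; ties resolved by transcript_id for determinism
            best = max(with_exons, key=lambda t: (t.span, t.transcript_id))
            start, end = best.start, best.end
        g2.transcripts.append(Transcript(
            transcript_id=g.gene_id + PREMRNA_SUFFIX,
            start=start, end=end, exons=[(start, end)]))
        out.append(g2)
    return out


def select_tss(genes: list[Gene], evidence: pd.DataFrame) -> pd.DataFrame:
    """One TSS per gene: the candidate maximizing summed rescaled evidence.

    Each of the three scores is min-max rescaled to [0, 1] across all
    candidates genome-wide before summing; exact ties go to the 5'-most
    candidate on the gene's strand.  Returns a table with 0-based
    coordinates; genes without candidates are excluded and logged.
    """
    required = {"gene_id", "chrom", "pos", "strand", "rnapii", "h3k4me3", "dnase"}
    missing = required - set(evidence.columns)
    if missing:
        raise ValueError(f"evidence table missing columns: {sorted(missing)}")
    ev = evidence.copy()
    for col in ("rnapii", "h3k4me3", "dnase"):
        if (ev[col] < 0).any():
            raise ValueError(f"negative evidence score in column {col}")
        lo, hi = ev[col].min(), ev[col].max()
        ev[col + "_scaled"] = 0.0 if hi == lo else (ev[col] - lo) / (hi - lo)
    ev["total"] = ev[["rnapii_scaled", "h3k4me3_scaled", "dnase_scaled"]].sum(axis=1)

    rows = []
    seen = set()
    for g in genes:
        cand = ev[ev["gene_id"] == g.gene_id]
        seen.add(g.gene_id)
        if cand.empty:
            logger.warning("gene %s has no TSS candidate; excluded", g.gene_id)
            continue
        best = cand[cand["total"] == cand["total"].max()]
        pos = int(best["pos"].min() if g.strand == "+" else best["pos"].max())
        rows.append({"gene_id": g.gene_id, "chrom": g.chrom, "pos": pos, "strand": g.strand})
    orphans = set(ev["gene_id"]) - seen
    if orphans:
        logger.warning("%d evidence rows reference unknown genes", len(orphans))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "pos", "strand"])


# ---------------------------------------------------------------------------
# expression filter
# ---------------------------------------------------------------------------

def filter_genes(expr: pd.DataFrame, sheet: pd.DataFrame, cfg: AnalysisConfig,
                 curated_ids: set[str]) -> list[str]:
    """Expression filter: curated AND (asynchronous mean TPM strictly above
    the threshold, OR above it in at least two individual post-mitotic
    release samples).  Gene order of the matrix is preserved."""
    if not curated_ids:
        raise ConfigurationError("curated id set is empty (configuration error, "
                                 "distinct from 'no gene passed')")
    sheet = sheet.set_index("sample_id")
    unknown = [s for s in expr.columns if s not in sheet.index]
    if unknown:
        raise ValueError(f"samples missing from sheet: {unknown[:5]}")
    async_cols = [s for s in expr.columns if sheet.loc[s, "state"] == "asynchronous"]
    release_cols = [s for s in expr.columns if sheet.loc[s, "state"] == "release"]
    async_ok = (expr[async_cols].mean(axis=1) > cfg.min_tpm) if async_cols else pd.Series(False, index=expr.index)
    release_ok = ((expr[release_cols] > cfg.min_tpm).sum(axis=1) >= 2) if release_cols else pd.Series(False, index=expr.index)
    keep = (async_ok | release_ok) & expr.index.isin(curated_ids)
    kept = [g for g in expr.index if keep.loc[g]]
    logger.info("filter_genes: %d/%d genes kept", len(kept), len(expr))
    return kept


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class TrajectorySet:
    """Per-gene replicate-averaged log2 fold changes to the mitotic anchor."""

    timepoints: tuple[int, ...]
    table: pd.DataFrame     # log2fc_async, lfc_<t> per timepoint, mean_fc_20_90
    zscores: pd.DataFrame   # columns: asynchronous, mitotic, t<t>...

    def lfc_columns(self) -> list[str]:
        return [f"lfc_{t}" for t in self.timepoints]


def _pair_to_mitotic(sheet: pd.DataFrame) -> dict[str, str]:
    """Map every asynchronous/release sample to its mitotic partner.

    Pairing is by (condition, replicate); a condition with a single mitotic
    pool pairs every sample to it.  Unpairable samples are a hard error.
    """
    pairs: dict[str, str] = {}
    for cond, sub in sheet.groupby("condition"):
        mito = sub[sub["state"] == "mitotic"]
        by_rep = {r: sid for r, sid in zip(mito["replicate"], mito["sample_id"])}
        for row in sub.itertuples(index=False):
            if row.state == "mitotic":
                continue
            if row.replicate in by_rep:
                pairs[row.sample_id] = by_rep[row.replicate]
            elif len(mito) == 1:
                pairs[row.sample_id] = mito["sample_id"].iloc[0]
            else:
                raise ValueError(
                    f"sample {row.sample_id!r} (condition {cond}, replicate "
                    f"{row.replicate}) has no mitotic partner")
    return pairs


def compute_sample_lfc(expr: pd.DataFrame, sheet: pd.DataFrame, cfg: AnalysisConfig,
                       condition: str = "untreated") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample log2((TPM + pc) / (mitotic TPM + pc)) for one arm.

    Returns (samples x genes matrix, matching sheet rows); the mitotic
    anchors themselves are excluded (their fold change is identically 0).
    """
    sub = sheet[sheet["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no samples for condition {condition!r}")
    pairs = _pair_to_mitotic(sub)
    pc = cfg.pseudocount_tpm
    rows, meta = [], []
    for row in sub.itertuples(index=False):
        if row.state == "mitotic":
            continue
        lfc = np.log2((expr[row.sample_id] + pc) / (expr[pairs[row.sample_id]] + pc))
        rows.append(lfc)
        meta.append(row._asdict() if hasattr(row, "_asdict") else dict(zip(sub.columns, row)))
    mat = pd.DataFrame(rows, index=[m["sample_id"] for m in meta])
    return mat, pd.DataFrame(meta)


def compute_trajectories(expr: pd.DataFrame, sheet: pd.DataFrame, cfg: AnalysisConfig,
                         condition: str = "untreated") -> TrajectorySet:
    """Replicate-wise fold changes to mitosis, then averaged per timepoint.

    The asynchronous anchor is computed identically from asynchronous
    samples.  z-scores are taken over the ordered vector (asynchronous
    anchor, mitotic anchor = 0, release timepoints); a missing timepoint
    stays absent (NaN), never imputed.
    """
    mat, meta = compute_sample_lfc(expr, sheet, cfg, condition)
    timepoints = tuple(sorted(int(t) for t in meta.loc[meta["state"] == "release", "time_min"].dropna().unique()))

    table = pd.DataFrame(index=expr.index)
    async_samples = meta.loc[meta["state"] == "asynchronous", "sample_id"]
    table["log2fc_async"] = mat.loc[async_samples].mean(axis=0) if len(async_samples) else np.nan
    for t in timepoints:
        samples = meta.loc[(meta["state"] == "release") & (meta["time_min"] == t), "sample_id"]
        table[f"lfc_{t}"] = mat.loc[samples].mean(axis=0)
    rank_cols = [f"lfc_{t}" for t in cfg.ranking_window if f"lfc_{t}" in table.columns]
    table["mean_fc_20_90"] = table[rank_cols].mean(axis=1) if rank_cols else np.nan

    vec = pd.DataFrame(index=expr.index)
    vec["asynchronous"] = table["log2fc_async"]
    vec["mitotic"] = 0.0
    for t in timepoints:
        vec[f"t{t}"] = table[f"lfc_{t}"]
    mu = vec.mean(axis=1)
    sd = vec.std(axis=1, ddof=0)
    z = vec.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    return TrajectorySet(timepoints=timepoints, table=table, zscores=z)


def rank_genes(traj: TrajectorySet) -> list[str]:
    """Descending mean 20-90 min fold change; ties break lexicographically."""
    tab = traj.table
    order = sorted(tab.index, key=lambda g: (-(tab.at[g, "mean_fc_20_90"]
                                              if np.isfinite(tab.at[g, "mean_fc_20_90"]) else -np.inf), g))
    return order
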