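"""Exact 2x2 tests, BH-FDR, and ranked-list sliding-window enrichment.

The one-sided (greater) Fisher p-value is the hypergeometric upper tail,
evaluated in log space so that extreme enrichments remain representable
(log10 p is reported alongside; p never silently underflows to an
unrepresented zero for tables with counts up to ~1e5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig

logger = logging.getLogger("mitoburst")

LN10 = np.log(10.0)


@dataclass
class FisherResult:
    p: float
    odds_ratio: float
    log10_p: float


def fisher_exact(a: int, b: int, c: int, d: int, sided: str = "greater") -> FisherResult:
    """Exact test on the 2x2 table [[a, b], [c, d]].

    Odds ratio is the sample (a*d)/(b*c) with the conventions: 0/0 -> NaN,
    x/0 -> inf.  ``greater`` tests enrichment of the a-cell given fixed
    margins (hypergeometric upper tail); ``two`` is the usual two-sided
    exact test.
    """
    counts = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in counts):
        raise ValueError(f"counts must be non-negative integers, got {counts}")
    a, b, c, d = (int(x) for x in counts)
    num, den = a * d, b * c
    if den > 0:
        oratio = num / den
    else:
        oratio = np.nan if num == 0 else np.inf

    total = a + b + c + d
    if sided == "greater":
        # X ~ Hypergeom(N=total, K=a+b, n=a+c); p = P(X >= a)
        if a == 0:
            log_p = 0.0  # P(X >= 0) = 1 exactly, even for empty tables
        else:
            log_p = min(stats.hypergeom.logsf(a - 1, total, a + b, a + c), 0.0)
        return FisherResult(p=float(np.exp(log_p)), odds_ratio=oratio,
                            log10_p=float(log_p / LN10))
    if sided == "two":
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        p = float(min(p, 1.0))
        return FisherResult(p=p, odds_ratio=oratio,
                            log10_p=float(np.log10(p)) if p > 0 else -np.inf)
    raise ValueError(f"sided must be 'greater' or 'two', got {sided!r}")


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _window_starts(n: int, window: int, step: int) -> list[int]:
    if window > n:
        raise ValueError(f"window {window} exceeds ranked-list length {n}")
    return list(range(0, n - window + 1, step))


def sliding_window_enrichment(ranked_genes: Sequence[str],
                              gene_sets: Mapping[str, set[str]],
                              cfg: AnalysisConfig,
                              sided: str = "greater",
                              fdr_family: str = "global") -> pd.DataFrame:
    """Fisher enrichment of each term in windows slid along a ranked list.

    Windows of ``enrich_window_genes`` genes advance by ``enrich_step_genes``
    from the top of the ranking.  Gene sets are intersected with the ranked
    universe first; BH correction spans all (window, term) pairs of the run
    (``fdr_family='per_term'`` restricts the family to each term instead).
    """
    ranked = list(ranked_genes)
    universe = set(ranked)
    n = len(ranked)
    window, step = cfg.enrich_window_genes, cfg.enrich_step_genes
    starts = _window_starts(n, window, step)
    rows = []
    for term, members in sorted(gene_sets.items()):
        in_set = members & universe
        if not in_set:
            logger.warning("term %s empty after intersection with universe; skipped", term)
            continue
        k_total = len(in_set)
        flags = np.fromiter((g in in_set for g in ranked), dtype=bool, count=n)
        csum = np.concatenate([[0], np.cumsum(flags)])
        for wi, s in enumerate(starts):
            a = int(csum[s + window] - csum[s])
            b = window - a
            c = k_total - a
            d = (n - window) - c
            res = fisher_exact(a, b, c, d, sided=sided)
            rows.append({"term": term, "window_index": wi, "start_rank": s,
                         "end_rank": s + window, "count_in_window": a,
                         "count_in_universe": k_total, "odds_ratio": res.odds_ratio,
                         "p": res.p, "log10_p": res.log10_p})
    track = pd.DataFrame(rows)
    if track.empty:
        track["fdr"] = []
        track["neg_log10_fdr"] = []
        return track
    if fdr_family == "global":
        track["fdr"] = bh_fdr(track["p"].to_numpy())
    elif fdr_family == "per_term":
        track["fdr"] = np.nan
        for term in track["term"].unique():
            sel = track["term"] == term
            track.loc[sel, "fdr"] = bh_fdr(track.loc[sel, "p"].to_numpy())
    else:
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    with np.errstate(divide="ignore"):
        track["neg_log10_fdr"] = -np.log10(track["fdr"])
    return track.sort_values(["term", "window_index"]).reset_index(drop=True)


def group_enrichment(group: Sequence[str], universe: Sequence[str],
                     gene_sets: Mapping[str, set[str]],
                     sided: str = "greater") -> pd.DataFrame:
    """One Fisher test per term for a fixed gene group against its universe."""
    group_set, uni = set(group), set(universe)
    offenders = sorted(group_set - uni)
    if offenders:
        raise ValueError(f"group genes outside the universe: {offenders[:10]}")
    if not group_set:
        logger.warning("empty gene group; returning empty enrichment table")
        return pd.DataFrame(columns=["term", "count_in_group", "group_size",
                                     "count_in_universe", "odds_ratio", "p", "log10_p", "fdr"])
    rows = []
    for term, members in sorted(gene_sets.items()):
        in_set = members & uni
        if not in_set:
            logger.warning("term %s empty after intersection with universe; skipped", term)
            continue
        a = len(group_set & in_set)
        b = len(group_set) - a
        c = len(in_set) - a
        d = len(uni) - len(group_set) - c
        res = fisher_exact(a, b, c, d, sided=sided)
        rows.append({"term": term, "count_in_group": a, "group_size": len(group_set),
                     "count_in_universe": len(in_set), "odds_ratio": res.odds_ratio,
                     "p": res.p, "log10_p": res.log10_p})
    table = pd.DataFrame(rows)
    if not table.empty:
        table["fdr"] = bh_fdr(table["p"].to_numpy())
    return table
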