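"""Differential response to acute factor depletion and its temporal classes.

Per contrast (asynchronous, or one release minute), the +IAA arm is tested
against the untreated arm on log2(TPM + pseudocount).  Two test flavours are
available:

``moderated`` (default)
    Empirical-Bayes moderated t: gene-wise pooled variances are shrunk
    toward a common prior fitted across all genes (scaled inverse-chi-square,
    method of moments), and the t statistic uses the posterior variance with
    augmented degrees of freedom.  With two replicates per arm this borrowed
    strength is what makes the test usable, mirroring how shared-dispersion
    count models behave on the real data.

``welch``
    Plain Welch two-sample t per gene; kept as the fully assumption-free
    variant.

Externally computed DE tables in the same schema can be imported and bypass
the stand-in entirely.  A gene responds if it passes the FDR and |log2FC|
cutoffs in the asynchronous contrast or in at least two release contrasts;
timing is early/late by the earliest qualifying release minute, ``asy`` if
the response is asynchronous-only.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats, optimize, special

from .config import AnalysisConfig
from .enrichment import bh_fdr

logger = logging.getLogger("mitoburst")

RESPONSE_TIMINGS = ("asy", "late", "early")
RESPONSE_DIRECTIONS = ("up", "down")


# ---------------------------------------------------------------------------
# variance shrinkage
# ---------------------------------------------------------------------------

def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Shrink gene-wise variances toward a fitted common prior.

    Fits a scaled inverse-chi-square prior (d0, s0^2) to the observed
    variances by matching moments of log s^2, then returns the posterior
    variances (d0*s0^2 + df*s^2) / (d0 + df) and the prior df d0
    (inf when the observed spread is no wider than sampling noise alone).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return s2.copy(), np.inf
    z = np.log(s2[ok])
    e_z = z.mean()
    var_z = z.var(ddof=1)
    excess = var_z - special.polygamma(1, df / 2.0)
    if excess <= 1e-12:
        d0 = np.inf
        log_s0 = e_z - special.digamma(df / 2.0) + np.log(df / 2.0)
    else:
        f = lambda d: special.polygamma(1, d / 2.0) - excess
        d0 = optimize.brentq(f, 1e-3, 1e8)
        log_s0 = (e_z - special.digamma(df / 2.0) + np.log(df / 2.0)
                  + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    s0_sq = float(np.exp(log_s0))
    if np.isinf(d0):
        post = np.full_like(s2, s0_sq)
    else:
        post = (d0 * s0_sq + df * s2) / (d0 + df)
    return post, d0


# ---------------------------------------------------------------------------
# DE testing
# ---------------------------------------------------------------------------

def _contrast_columns(sheet: pd.DataFrame, contrast: str) -> tuple[list[str], list[str]]:
    if contrast == "asynchronous":
        sel = sheet["state"] == "asynchronous"
    else:
        sel = (sheet["state"] == "release") & (sheet["time_min"] == float(contrast))
    iaa = sheet.loc[sel & (sheet["condition"] == "IAA"), "sample_id"].tolist()
    ctrl = sheet.loc[sel & (sheet["condition"] == "untreated"), "sample_id"].tolist()
    return iaa, ctrl


def de_test(expr: pd.DataFrame, sheet: pd.DataFrame, cfg: AnalysisConfig,
            genes: list[str] | None = None, method: str = "moderated") -> pd.DataFrame:
    """Per-contrast differential test of +IAA vs untreated.

    Returns one row per gene per contrast with log2fc (+IAA over untreated),
    p, and BH fdr computed within each contrast.  Contrasts with fewer than
    two replicates in an arm are skipped with a warning.
    """
    if method not in ("moderated", "welch"):
        raise ValueError(f"unknown method {method!r}")
    if genes is not None:
        expr = expr.loc[genes]
    contrasts = ["asynchronous"] + [str(int(t)) for t in sorted(
        sheet.loc[sheet["state"] == "release", "time_min"].dropna().unique())]
    pc = cfg.pseudocount_tpm
    log_expr = np.log2(expr + pc)
    out = []
    for contrast in contrasts:
        iaa, ctrl = _contrast_columns(sheet, contrast)
        if len(iaa) < 2 or len(ctrl) < 2:
            logger.warning("contrast %s skipped: <2 replicates in an arm "
                           "(+IAA n=%d, untreated n=%d)", contrast, len(iaa), len(ctrl))
            continue
        x = log_expr[iaa].to_numpy()
        y = log_expr[ctrl].to_numpy()
        n1, n2 = x.shape[1], y.shape[1]
        lfc = x.mean(axis=1) - y.mean(axis=1)
        if method == "welch":
            with np.errstate(invalid="ignore", divide="ignore"):
                t, p = stats.ttest_ind(x, y, axis=1, equal_var=False)
            p = np.where(np.isfinite(p), p, 1.0)
        else:
            df = n1 + n2 - 2
            s2 = (x.var(axis=1, ddof=1) * (n1 - 1) + y.var(axis=1, ddof=1) * (n2 - 1)) / df
            post, d0 = squeeze_variances(s2, df)
            df_total = df + (d0 if np.isfinite(d0) else 1e6)
            se = np.sqrt(post * (1.0 / n1 + 1.0 / n2))
            with np.errstate(invalid="ignore", divide="ignore"):
                t = lfc / se
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
            p = np.where(se > 0, p, 1.0)  # degenerate: no variance anywhere
        frame = pd.DataFrame({"gene_id": expr.index, "contrast": contrast,
                              "log2fc": lfc, "p": p, "fdr": bh_fdr(p)})
        out.append(frame)
    if not out:
        return pd.DataFrame(columns=["gene_id", "contrast", "log2fc", "p", "fdr"])
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# response classification
# ---------------------------------------------------------------------------

def classify_response(de: pd.DataFrame, cfg: AnalysisConfig) -> pd.DataFrame:
    """Assign timing x direction classes from a DE table.

    A gene responds iff it passes (fdr < de_fdr and |log2fc| > de_abs_lfc)
    in the asynchronous contrast OR in >=2 release contrasts.  Timing:
    ``early`` if the earliest qualifying release minute is <= early_max_min,
    ``late`` if release support exists but only from later minutes, ``asy``
    if only the asynchronous contrast qualifies.  Genes whose qualifying
    contrasts disagree in sign are flagged discordant and excluded from the
    six classes.  Invariant to the row order of the DE table.
    """
    de = de.copy()
    de["qualifies"] = (de["fdr"] < cfg.de_fdr) & (de["log2fc"].abs() > cfg.de_abs_lfc)
    rows = []
    for gid, sub in de.groupby("gene_id", sort=True):
        q = sub[sub["qualifies"]]
        async_hit = "asynchronous" in set(q["contrast"])
        release_hits = sorted(int(c) for c in q["contrast"] if c != "asynchronous")
        release_de = len(release_hits) >= 2
        if not (async_hit or release_de):
            continue
        signs = set(np.sign(q["log2fc"]))
        support = ",".join(sorted(q["contrast"], key=lambda c: (c != "asynchronous",
                                                                int(c) if c != "asynchronous" else 0)))
        if len(signs) > 1:
            rows.append({"gene_id": gid, "timing": "discordant", "direction": "discordant",
                         "n_support": len(q), "supporting_contrasts": support})
            continue
        direction = "up" if signs.pop() > 0 else "down"
        if release_de:
            timing = "early" if release_hits[0] <= cfg.early_max_min else "late"
        else:
            timing = "asy"
        rows.append({"gene_id": gid, "timing": timing, "direction": direction,
                     "n_support": len(q), "supporting_contrasts": support})
    return pd.DataFrame(rows, columns=["gene_id", "timing", "direction",
                                       "n_support", "supporting_contrasts"])


def response_group_summary(classes: pd.DataFrame,
                           zscores_by_arm: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per class, arm, and sample label: median, quartiles, and 1.5-IQR
    whisker bounds of gene z-scored trajectories."""
    rows = []
    classes = classes[classes["timing"] != "discordant"]
    for (timing, direction), sub in classes.groupby(["timing", "direction"], sort=True):
        cls = f"{timing}_{direction}"
        for arm, z in sorted(zscores_by_arm.items()):
            genes = [g for g in sub["gene_id"] if g in z.index]
            if not genes:
                rows.append({"class": cls, "arm": arm, "sample": "", "n_genes": 0,
                             "median": np.nan, "q1": np.nan, "q3": np.nan,
                             "whisker_lo": np.nan, "whisker_hi": np.nan})
                continue
            zi = z.loc[genes]
            for col in z.columns:
                vals = zi[col].dropna()
                q1, med, q3 = np.percentile(vals, [25, 50, 75]) if len(vals) else (np.nan,) * 3
                iqr = q3 - q1
                rows.append({"class": cls, "arm": arm, "sample": col, "n_genes": len(genes),
                             "median": med, "q1": q1, "q3": q3,
                             "whisker_lo": q1 - 1.5 * iqr, "whisker_hi": q3 + 1.5 * iqr})
    return pd.DataFrame(rows)
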