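"""Synthetic mitotic-release time course with planted ground truth.

The generator emulates the measured design of a nocodazole-release
experiment in ES cells: asynchronous (A) and mitotic (M) reference pools
plus a dense post-release grid (20-120 min), quantified as pre-mRNA TPM,
optionally in two arms (untreated vs. acute CTCF depletion with auxin, +IAA).

Each gene follows one of six kinetic programs:

``fast_burst``      strong transcriptional burst starting 20-30 min after
                    release, reaching asynchronous levels by ~40 min
``slow_sustained``  later onset (40-60 min), sustained
``g1_specific``     low in asynchronous populations, burst after mitosis
                    (preferential early-G1 transcription)
``s_phase_like``    histone-like: maximal in asynchronous (S-phase-rich)
                    populations, reactivating from ~50 min
``late``            reaching asynchronous levels at 120 min or never
``silent``          below the expression filter in every state

The mean signal is piecewise: flat at the mitotic baseline before onset,
jumping to ``amplitude x baseline`` at onset and decaying back with the
given half-life (infinite half-life = sustained plateau).  Replicate noise
is multiplicative log-normal.  CTCF dependence is a multiplicative factor
applied to the +IAA arm over a class-specific set of samples.  Peak sets
plant promoter-proximal mitotically retained (Book) binding sites near
early-responsive genes, on top of a uniform background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig, ConfigurationError, SimDesign, to_yaml
from . import io as mio

CLASS_LABELS = ("fast_burst", "slow_sustained", "g1_specific",
                "s_phase_like", "silent", "late")
CTCF_ONSETS = ("asynchronous_only", "early", "late")

# class mixture mirroring the published composition of the reactivation
# classes (~1/3 fast, ~8% G1-specific, ~10% asynchronous-maximal, few late)
DEFAULT_CLASS_FRACTIONS = {
    "fast_burst": 0.32,
    "slow_sustained": 0.25,
    "g1_specific": 0.08,
    "s_phase_like": 0.10,
    "late": 0.05,
    "silent": 0.20,
}

# planted depletion-response mixture: timing x direction, fraction of genes
DEFAULT_RESPONSE_FRACTIONS = {
    "early_down": 0.03,
    "early_up": 0.015,
    "late_down": 0.015,
    "late_up": 0.01,
    "asy_down": 0.005,
    "asy_up": 0.005,
}

DEFAULT_CHROM_SIZES = {"chrS1": 20_000_000, "chrS2": 20_000_000, "chrS3": 20_000_000}
DEFAULT_NOISE_SD_LOG2 = 0.25
DEFAULT_CTCF_EFFECT = {"down": 0.5, "up": 2.0}


@dataclass
class GeneProgram:
    """Kinetic program of one simulated gene."""

    gene_id: str
    class_label: str
    onset_min: float
    amplitude: float            # fold over the mitotic baseline at onset
    persistence_min: float      # decay half-life; inf = sustained
    async_level: float          # TPM in asynchronous samples
    mitotic_level: float        # TPM in mitotic samples
    ctcf_effect: float = 1.0    # multiplicative factor in the +IAA arm
    ctcf_effect_onset: str = "early"

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class_label {self.class_label!r} for gene {self.gene_id}")
        if self.ctcf_effect_onset not in CTCF_ONSETS:
            raise ValueError(f"unknown ctcf_effect_onset {self.ctcf_effect_onset!r} for gene {self.gene_id}")
        if not self.amplitude > 0:
            raise ValueError(f"amplitude must be > 0 (gene {self.gene_id})")
        if self.async_level < 0 or self.mitotic_level < 0:
            raise ValueError(f"expression levels must be >= 0 (gene {self.gene_id})")

    def mean_release(self, t_min: float) -> float:
        """Noise-free mean TPM at ``t_min`` after release."""
        if t_min < self.onset_min:
            return self.mitotic_level
        peak = self.amplitude * self.mitotic_level
        if np.isinf(self.persistence_min):
            return peak
        decay = 2.0 ** (-(t_min - self.onset_min) / self.persistence_min)
        return self.mitotic_level + (peak - self.mitotic_level) * decay


# ---------------------------------------------------------------------------
# program sampling
# ---------------------------------------------------------------------------

def _draw_class_params(label: str, rng: np.random.Generator) -> dict:
    m = float(np.exp(rng.normal(np.log(3.0), 0.5)))  # mitotic baseline TPM
    if label == "fast_burst":
        amp = float(rng.uniform(6, 12))
        return dict(onset_min=float(rng.choice([20, 30])), amplitude=amp,
                    persistence_min=np.inf, mitotic_level=m,
                    async_level=m * amp * float(rng.uniform(0.55, 0.85)))
    if label == "slow_sustained":
        amp = float(rng.uniform(3, 6))
        return dict(onset_min=float(rng.choice([40, 50, 60])), amplitude=amp,
                    persistence_min=np.inf, mitotic_level=m,
                    async_level=m * amp * float(rng.uniform(0.6, 0.9)))
    if label == "g1_specific":
        amp = float(rng.uniform(4, 8))
        return dict(onset_min=float(rng.choice([20, 30])), amplitude=amp,
                    persistence_min=float(rng.uniform(60, 120)), mitotic_level=m,
                    async_level=m * float(rng.uniform(0.2, 0.6)))
    if label == "s_phase_like":
        amp = float(rng.uniform(2, 4))
        return dict(onset_min=50.0, amplitude=amp,
                    persistence_min=np.inf, mitotic_level=m,
                    async_level=m * amp * float(rng.uniform(1.5, 2.5)))
    if label == "late":
        amp = float(rng.uniform(3, 5))
        return dict(onset_min=float(rng.choice([120, 150])), amplitude=amp,
                    persistence_min=np.inf, mitotic_level=m,
                    async_level=m * amp * float(rng.uniform(0.6, 0.9)))
    if label == "silent":
        return dict(onset_min=20.0, amplitude=1.0, persistence_min=np.inf,
                    mitotic_level=0.05, async_level=0.05)
    raise ValueError(label)


def default_programs(
    gene_ids: Sequence[str],
    seed: int,
    class_fractions: Mapping[str, float] | None = None,
    response_fractions: Mapping[str, float] | None = None,
    ctcf_effect: Mapping[str, float] | None = None,
) -> list[GeneProgram]:
    """Sample the default mixture of kinetic programs and planted responses."""
    fractions = dict(class_fractions or DEFAULT_CLASS_FRACTIONS)
    responses = dict(response_fractions or DEFAULT_RESPONSE_FRACTIONS)
    effects = dict(ctcf_effect or DEFAULT_CTCF_EFFECT)
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ConfigurationError("class fractions must sum to 1")
    rng = np.random.default_rng([int(seed) % (2**31), 11])
    n = len(gene_ids)
    labels = np.concatenate([
        np.repeat(lab, int(round(frac * n))) for lab, frac in sorted(fractions.items())
    ])
    labels = labels[:n] if len(labels) >= n else np.concatenate(
        [labels, np.repeat("silent", n - len(labels))])
    rng.shuffle(labels)

    programs = [
        GeneProgram(gene_id=g, class_label=str(lab), **_draw_class_params(str(lab), rng))
        for g, lab in zip(gene_ids, labels)
    ]
    # plant depletion responses on expressed (non-silent) genes
    candidates = [i for i, p in enumerate(programs) if p.class_label != "silent"]
    rng.shuffle(candidates)
    pos = 0
    for resp, frac in sorted(responses.items()):
        k = int(round(frac * n))
        timing, direction = resp.rsplit("_", 1)
        onset = {"asy": "asynchronous_only", "early": "early", "late": "late"}[timing]
        for i in candidates[pos:pos + k]:
            programs[i].ctcf_effect = effects[direction]
            programs[i].ctcf_effect_onset = onset
        pos += k
    return programs


def truth_table(programs: Sequence[GeneProgram]) -> pd.DataFrame:
    """Planted ground truth, one row per gene (round-trips through TSV)."""
    rows = []
    for p in programs:
        if p.ctcf_effect == 1.0:
            resp = "none"
        else:
            timing = {"asynchronous_only": "asy", "early": "early", "late": "late"}[p.ctcf_effect_onset]
            resp = f"{timing}_{'down' if p.ctcf_effect < 1 else 'up'}"
        rows.append({
            "gene_id": p.gene_id, "class_label": p.class_label,
            "onset_min": p.onset_min, "amplitude": p.amplitude,
            "persistence_min": p.persistence_min,
            "async_level": p.async_level, "mitotic_level": p.mitotic_level,
            "ctcf_effect": p.ctcf_effect, "ctcf_effect_onset": p.ctcf_effect_onset,
            "response_class": resp,
            "planted_gene_sets": "", "planted_peak_distance_bp": np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(
    n_genes: int,
    chrom_sizes: Mapping[str, int] | None = None,
    isoforms_per_gene: tuple[int, int] = (1, 3),
    seed: int = 0,
) -> tuple[list[mio.Gene], pd.DataFrame]:
    """Random gene models plus per-TSS evidence scores.

    Returns the gene models and a candidate-TSS table with three
    non-negative evidence scores (RNAPII, H3K4me3, DNaseI) per candidate,
    feeding the evidence-weighted TSS selection downstream.
    """
    chrom_sizes = dict(DEFAULT_CHROM_SIZES) if chrom_sizes is None else dict(chrom_sizes)
    if not chrom_sizes:
        raise ConfigurationError("chrom_sizes must name at least one chromosome")
    if any(s <= 0 for s in chrom_sizes.values()):
        raise ConfigurationError("chromosome sizes must be positive")
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    lo, hi = isoforms_per_gene
    if not (1 <= lo <= hi):
        raise ConfigurationError("isoforms_per_gene must be a range with 1 <= lo <= hi")

    rng = np.random.default_rng([int(seed) % (2**31), 7])
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights = sizes / sizes.sum()
    width = max(len(str(n_genes)), 4)

    genes: list[mio.Gene] = []
    ev_rows: list[dict] = []
    for i in range(n_genes):
        gid = f"g{i + 1:0{width}d}"
        ci = int(rng.choice(len(chroms), p=weights))
        chrom, csize = chroms[ci], int(sizes[ci])
        glen = int(rng.integers(2_000, min(20_000, csize)))
        gstart = int(rng.integers(0, csize - glen))
        strand = "+" if rng.random() < 0.5 else "-"
        k = int(rng.integers(lo, hi + 1))
        transcripts = []
        for j in range(k):
            if j == 0:
                ts, te = gstart, gstart + glen
            else:
                span = int(rng.integers(max(200, glen // 4), glen + 1))
                ts = gstart + int(rng.integers(0, glen - span + 1))
                te = ts + span
            exlen = max(50, (te - ts) // 5)
            if te - ts > 2 * exlen + 100:
                exons = [(ts, ts + exlen), (te - exlen, te)]
            else:
                exons = [(ts, te)]
            transcripts.append(mio.Transcript(f"{gid}.t{j + 1}", ts, te, exons))
        genes.append(mio.Gene(gid, chrom, strand, transcripts))
        for t in transcripts:
            pos = t.start if strand == "+" else t.end - 1
            ev_rows.append({
                "gene_id": gid, "transcript_id": t.transcript_id,
                "chrom": chrom, "pos": pos, "strand": strand,
                "rnapii": float(rng.exponential(1.0)),
                "h3k4me3": float(rng.exponential(1.0)),
                "dnase": float(rng.exponential(1.0)),
            })
    return genes, pd.DataFrame(ev_rows)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def build_sample_sheet(design: SimDesign) -> pd.DataFrame:
    rows = []
    for cond in design.conditions:
        for r in range(1, design.n_rep_async + 1):
            rows.append((f"{cond}_A_r{r}", cond, "asynchronous", np.nan, f"r{r}"))
        for r in range(1, design.n_rep_mitotic + 1):
            rows.append((f"{cond}_M_r{r}", cond, "mitotic", np.nan, f"r{r}"))
        for t in design.timepoints_min:
            for r in range(1, design.n_rep_release + 1):
                rows.append((f"{cond}_t{t:03d}_r{r}", cond, "release", float(t), f"r{r}"))
    return pd.DataFrame(rows, columns=["sample_id", "condition", "state", "time_min", "replicate"])


def _iaa_multiplier(program: GeneProgram, state: str, t: float | None) -> float:
    if program.ctcf_effect == 1.0:
        return 1.0
    onset = program.ctcf_effect_onset
    if state == "asynchronous":
        return program.ctcf_effect
    if state == "release":
        if onset == "early":
            return program.ctcf_effect
        if onset == "late" and t is not None and t >= 50:
            return program.ctcf_effect
    return 1.0


def generate_expression(
    programs: Sequence[GeneProgram],
    design: SimDesign,
    noise_sd_log2: float = DEFAULT_NOISE_SD_LOG2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noise-free kinetic means plus multiplicative log-normal noise.

    The noise matrix is drawn from its own stream keyed only on the seed and
    the matrix shape, so changing a program parameter never reshuffles the
    noise of unrelated entries (mean responses are monotone in amplitude
    under a fixed seed).
    """
    if noise_sd_log2 < 0:
        raise ConfigurationError("noise_sd_log2 must be >= 0")
    sheet = build_sample_sheet(design)
    mu = np.empty((len(programs), len(sheet)), dtype=float)
    for gi, p in enumerate(programs):
        for si, row in enumerate(sheet.itertuples(index=False)):
            if row.state == "asynchronous":
                base = p.async_level
            elif row.state == "mitotic":
                base = p.mitotic_level
            else:
                base = p.mean_release(row.time_min)
            if row.condition == "IAA":
                base *= _iaa_multiplier(p, row.state, row.time_min)
            mu[gi, si] = base
    noise_rng = np.random.default_rng([int(seed) % (2**31), 23])
    eps = noise_rng.normal(0.0, noise_sd_log2, size=mu.shape)
    tpm = mu * np.exp2(eps)
    expr = pd.DataFrame(tpm, index=[p.gene_id for p in programs],
                        columns=sheet["sample_id"].tolist())
    expr.index.name = "gene_id"
    return expr, sheet


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def generate_peaks(
    tss: pd.DataFrame,
    truth: pd.DataFrame,
    p_book_near_early: float = 0.8,
    background_rate_per_mb: float = 50.0,
    seed: int = 0,
    chrom_sizes: Mapping[str, int] | None = None,
    p_book_background: float = 0.3,
    planted_distance_scale_bp: float = 2_000.0,
) -> tuple[mio.PeakSet, mio.PeakSet, pd.DataFrame]:
    """Interphase + mitotic peak sets with promoter-proximal planting.

    Mitotic binding is a strict subset of interphase binding (the Book/Lost
    dichotomy): every mitotic peak is nested inside an interphase peak.
    Genes with a planted early depletion response receive a Book peak near
    their TSS with probability ``p_book_near_early``; the offset is signed
    exponential with the given scale.  Returns the two peak sets and the
    truth table updated with the planted TSS-to-peak distances.
    """
    if len(tss) == 0:
        raise ConfigurationError("TSS list is empty")
    for p in (p_book_near_early, p_book_background):
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError("probabilities must be within [0, 1]")
    if background_rate_per_mb < 0:
        raise ConfigurationError("background rate must be >= 0")
    chrom_sizes = dict(DEFAULT_CHROM_SIZES) if chrom_sizes is None else dict(chrom_sizes)
    rng = np.random.default_rng([int(seed) % (2**31), 31])

    inter_rows: list[dict] = []
    mito_rows: list[dict] = []

    def add_peak(chrom: str, center: int, height: float, book: bool) -> tuple[int, int]:
        csize = chrom_sizes[chrom]
        half = int(rng.integers(100, 400))
        start = max(0, min(center - half, csize - 2 * half - 1))
        end = min(csize, start + 2 * half)
        inter_rows.append({"chrom": chrom, "start": start, "end": end, "height": height})
        if book:
            shrink = int((end - start) * rng.uniform(0.0, 0.2))
            mito_rows.append({"chrom": chrom, "start": start + shrink // 2,
                              "end": end - shrink // 2,
                              "height": height * rng.uniform(0.3, 0.8)})
        return start, end

    # uniform background
    for chrom in sorted(chrom_sizes):
        n_bg = rng.poisson(background_rate_per_mb * chrom_sizes[chrom] / 1e6)
        centers = np.sort(rng.integers(0, chrom_sizes[chrom], size=n_bg))
        for c in centers:
            add_peak(chrom, int(c), float(np.exp(rng.normal(np.log(3.0), 0.6))),
                     bool(rng.random() < p_book_background))

    # planted promoter-proximal Book sites near early responders
    truth = truth.set_index("gene_id", drop=False)
    planted_dist = pd.Series(np.nan, index=truth.index, dtype=float)
    early_ids = truth.index[truth["response_class"].str.startswith("early")]
    tss_idx = tss.set_index("gene_id")
    for gid in early_ids:
        if gid not in tss_idx.index or rng.random() >= p_book_near_early:
            continue
        row = tss_idx.loc[gid]
        offset = int(rng.exponential(planted_distance_scale_bp)) * (1 if rng.random() < 0.5 else -1)
        center = int(row["pos"]) + offset
        height = 2.0 * float(np.exp(rng.normal(np.log(3.0), 0.6)))
        s, e = add_peak(str(row["chrom"]), center, height, book=True)
        t = int(row["pos"])
        planted_dist.loc[gid] = float(max(s - t, t - e + 1, 0))

    def finish(rows: list[dict], prefix: str) -> mio.PeakSet:
        if not rows:
            df = pd.DataFrame(columns=["chrom", "start", "end", "peak_id", "height"])
        else:
            df = pd.DataFrame(rows).sort_values(["chrom", "start", "end"]).reset_index(drop=True)
            df["peak_id"] = [f"{prefix}_{i + 1:05d}" for i in range(len(df))]
            df = df[["chrom", "start", "end", "peak_id", "height"]]
        return mio.PeakSet(df=df, condition="interphase" if prefix == "ip" else "mitotic")

    truth = truth.reset_index(drop=True).copy()
    truth["planted_peak_distance_bp"] = planted_dist.to_numpy()
    return finish(inter_rows, "ip"), finish(mito_rows, "mt"), truth


# ---------------------------------------------------------------------------
# coverage + gene sets
# ---------------------------------------------------------------------------

def peaks_to_coverage(peaks: mio.PeakSet, chrom_sizes: Mapping[str, int]) -> tuple[pd.DataFrame, float]:
    """Piecewise-constant coverage summing peak heights; returns (bedGraph, library size).

    The nominal library size is the coverage integral divided by a 50-bp
    read length, the convention used when scaling profiles to RPM.
    """
    rows = []
    for chrom in sorted(chrom_sizes):
        sub = peaks.df[peaks.df["chrom"] == chrom]
        if sub.empty:
            continue
        edges = np.unique(np.concatenate([sub["start"].to_numpy(), sub["end"].to_numpy()]))
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        heights = sub["height"].to_numpy()
        for a, b in zip(edges[:-1], edges[1:]):
            cov = float(heights[(starts <= a) & (ends >= b)].sum())
            if cov > 0:
                rows.append({"chrom": chrom, "start": int(a), "end": int(b), "value": cov})
    cov_df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    integral = float(((cov_df["end"] - cov_df["start"]) * cov_df["value"]).sum()) if len(cov_df) else 0.0
    return cov_df, max(integral / 50.0, 1.0)


def generate_gene_sets(truth: pd.DataFrame, seed: int = 0,
                       n_random: int = 3, random_size: int = 200) -> dict[str, set[str]]:
    """GMT-ready gene sets: planted class-derived terms plus random nulls."""
    rng = np.random.default_rng([int(seed) % (2**31), 43])
    ids = truth["gene_id"].to_numpy()
    sets: dict[str, set[str]] = {}
    for label, name in (("fast_burst", "planted_fast_reactivation"),
                        ("g1_specific", "planted_g1_program"),
                        ("s_phase_like", "planted_s_phase")):
        members = truth.loc[truth["class_label"] == label, "gene_id"].to_numpy()
        take = members[rng.random(len(members)) < 0.8]
        contam = ids[rng.random(len(ids)) < 0.01]
        sets[name] = set(take) | set(contam)
    for k in range(1, n_random + 1):
        sets[f"random_null_{k}"] = set(rng.choice(ids, size=min(random_size, len(ids)), replace=False))
    return sets


# ---------------------------------------------------------------------------
# one-call simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    design: SimDesign
    programs: list[GeneProgram]
    genes: list[mio.Gene]
    evidence: pd.DataFrame
    expression: pd.DataFrame
    sample_sheet: pd.DataFrame
    peaks_interphase: mio.PeakSet
    peaks_mitotic: mio.PeakSet
    coverage: pd.DataFrame
    library_size: float
    gene_sets: dict[str, set[str]]
    truth: pd.DataFrame
    chrom_sizes: dict[str, int] = field(default_factory=dict)


def simulate_run(
    n_genes: int = 2_000,
    design: SimDesign | None = None,
    seed: int = 0,
    noise_sd_log2: float = DEFAULT_NOISE_SD_LOG2,
    chrom_sizes: Mapping[str, int] | None = None,
    p_book_near_early: float = 0.8,
    background_rate_per_mb: float = 50.0,
    class_fractions: Mapping[str, float] | None = None,
    response_fractions: Mapping[str, float] | None = None,
) -> SimulationResult:
    """Generate a complete synthetic study (annotation, expression, peaks,
    coverage, gene sets, truth) from a single seed."""
    design = design or SimDesign(conditions=("untreated", "IAA"), seed=seed)
    chrom_sizes = dict(DEFAULT_CHROM_SIZES) if chrom_sizes is None else dict(chrom_sizes)
    genes, evidence = generate_annotation(n_genes, chrom_sizes, seed=seed)
    programs = default_programs([g.gene_id for g in genes], seed=seed,
                                class_fractions=class_fractions,
                                response_fractions=response_fractions)
    expr, sheet = generate_expression(programs, design, noise_sd_log2, seed=seed)
    truth = truth_table(programs)
    # primary TSS = 5' end of the longest transcript (evidence scores refine
    # this downstream; planting only needs an approximate promoter location)
    tss_rows = []
    for g in genes:
        t = max(g.transcripts, key=lambda t: t.span)
        tss_rows.append({"gene_id": g.gene_id, "chrom": g.chrom,
                         "pos": t.start if g.strand == "+" else t.end - 1,
                         "strand": g.strand})
    tss = pd.DataFrame(tss_rows)
    inter, mito, truth = generate_peaks(
        tss, truth, p_book_near_early=p_book_near_early,
        background_rate_per_mb=background_rate_per_mb, seed=seed,
        chrom_sizes=chrom_sizes)
    gene_sets = generate_gene_sets(truth, seed=seed)
    truth["planted_gene_sets"] = [
        ",".join(sorted(name for name, members in gene_sets.items() if gid in members))
        for gid in truth["gene_id"]
    ]
    coverage, library_size = peaks_to_coverage(inter, chrom_sizes)
    return SimulationResult(
        design=design, programs=programs, genes=genes, evidence=evidence,
        expression=expr, sample_sheet=sheet, peaks_interphase=inter,
        peaks_mitotic=mito, coverage=coverage, library_size=library_size,
        gene_sets=gene_sets, truth=truth, chrom_sizes=chrom_sizes)


def write_outputs(sim: SimulationResult, outdir: str | Path, seed: int | None = None) -> None:
    """Serialize every simulated artifact into ``outdir`` (all plain text)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    prov = [f"mitoburst simulate seed={seed}"] if seed is not None else []
    mio.write_gtf(sim.genes, out / "annotation.gtf", header=prov)
    mio.write_expression(sim.expression, out / "expression_tpm.tsv", header=prov)
    mio.write_sample_sheet(sim.sample_sheet, out / "samples.tsv", header=prov)
    mio.write_table(sim.evidence, out / "tss_evidence.tsv", header=prov)
    mio.write_peaks(sim.peaks_interphase, out / "peaks_interphase.bed", header=prov)
    mio.write_peaks(sim.peaks_mitotic, out / "peaks_mitotic.bed", header=prov)
    mio.write_bedgraph(sim.coverage, out / "coverage.bedgraph", header=prov)
    mio.write_gmt(sim.gene_sets, out / "gene_sets.gmt")
    mio.write_table(sim.truth, out / "truth.tsv", header=prov)
    (out / "library_size.txt").write_text(f"{sim.library_size:.1f}\n")
    (out / "curated_ids.txt").write_text(
        "\n".join(g.gene_id for g in sim.genes) + "\n")
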