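"""Configuration objects for the simulation design and the analysis parameters.

All tunable constants of the pipeline live in two frozen-by-convention
dataclasses: :class:`SimDesign` (the sampling design of the time course) and
:class:`AnalysisConfig` (filter thresholds, window sizes, test cutoffs).
Both round-trip through a single YAML document so that one config file drives
an entire run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

RELEASE_TIMEPOINTS = (20, 30, 40, 50, 60, 90, 120)


class ConfigurationError(ValueError):
    """Raised when a config value violates its documented invariant."""


@dataclass
class SimDesign:
    """Sampling design of the mitotic-release time course.

    Mirrors the measured design: asynchronous (A) and mitotic (M) reference
    pools with 3 replicates each, and 2 replicates per post-release timepoint,
    optionally duplicated over an auxin (+IAA) depletion arm.
    """

    timepoints_min: tuple[int, ...] = RELEASE_TIMEPOINTS
    n_rep_async: int = 3
    n_rep_mitotic: int = 3
    n_rep_release: int = 2
    conditions: tuple[str, ...] = ("untreated",)
    seed: int = 0

    def __post_init__(self) -> None:
        self.timepoints_min = tuple(int(t) for t in self.timepoints_min)
        self.conditions = tuple(self.conditions)
        if any(b <= a for a, b in zip(self.timepoints_min, self.timepoints_min[1:])):
            raise ConfigurationError("timepoints_min must be strictly increasing")
        if min(self.n_rep_async, self.n_rep_mitotic, self.n_rep_release) < 1:
            raise ConfigurationError("replicate counts must be >= 1")
        bad = set(self.conditions) - {"untreated", "IAA"}
        if bad or not self.conditions:
            raise ConfigurationError(f"conditions must be a non-empty subset of untreated/IAA, got {self.conditions}")

    @property
    def n_samples_per_condition(self) -> int:
        return self.n_rep_async + self.n_rep_mitotic + self.n_rep_release * len(self.timepoints_min)


@dataclass
class AnalysisConfig:
    """Thresholds and window sizes used throughout the analysis.

    min_tpm            expression filter: mean TPM across asynchronous samples
                       strictly above this, or above it in >=2 individual
                       post-mitotic samples
    pseudocount_tpm    added to TPM before every log2 ratio
    ranking_window     release minutes averaged to rank genes (mean of 20-90)
    tss_window_bp      width of the TSS-centred window for peak association
    loading_group_size genes per PCA loading group (PC1t/PC1b/PC2t/PC2b)
    enrich_window_genes / enrich_step_genes   ranked-list sliding window
    de_fdr, de_abs_lfc differential-response call thresholds
    metagene_span_bp / metagene_bin_bp        metagene profile geometry
    distance_grid_kb   strata for distance-stratified Fisher tests
    early_max_min      latest release minute still counted as an "early"
                       depletion response
    """

    min_tpm: float = 0.5
    pseudocount_tpm: float = 1.0
    ranking_window: tuple[int, ...] = (20, 30, 40, 50, 60, 90)
    tss_window_bp: int = 25_000
    loading_group_size: int = 1_000
    enrich_window_genes: int = 500
    enrich_step_genes: int = 50
    de_fdr: float = 0.1
    de_abs_lfc: float = 0.2
    metagene_span_bp: int = 8_000
    metagene_bin_bp: int = 50
    distance_grid_kb: tuple[float, ...] = (1, 2.5, 5, 10, 25, 50, 100, 250, 500, 1000)
    early_max_min: int = 40

    def __post_init__(self) -> None:
        self.ranking_window = tuple(int(t) for t in self.ranking_window)
        self.distance_grid_kb = tuple(float(d) for d in self.distance_grid_kb)
        numeric = (
            self.min_tpm, self.pseudocount_tpm, self.tss_window_bp,
            self.loading_group_size, self.enrich_window_genes,
            self.enrich_step_genes, self.de_fdr, self.de_abs_lfc,
            self.metagene_span_bp, self.metagene_bin_bp, self.early_max_min,
        )
        if any(v <= 0 for v in numeric):
            raise ConfigurationError("all AnalysisConfig scalars must be positive")
        if any(d <= 0 for d in self.distance_grid_kb):
            raise ConfigurationError("distance grid must be positive")
        if self.metagene_span_bp % self.metagene_bin_bp != 0:
            raise ConfigurationError("metagene_span_bp must be a multiple of metagene_bin_bp")
        if (self.metagene_span_bp // self.metagene_bin_bp) % 2 != 0:
            raise ConfigurationError("metagene window must hold an even number of bins")


def to_yaml(design: SimDesign, cfg: AnalysisConfig) -> str:
    doc = {"sim": asdict(design), "analysis": asdict(cfg)}
    return yaml.safe_dump(doc, sort_keys=True)


def from_yaml(text: str) -> tuple[SimDesign, AnalysisConfig]:
    doc = yaml.safe_load(text) or {}
    if not isinstance(doc, dict):
        raise ConfigurationError("config document must be a mapping")
    known = {"sim", "analysis"}
    extra = set(doc) - known
    if extra:
        raise ConfigurationError(f"unknown config section(s): {sorted(extra)}")
    try:
        design = SimDesign(**(doc.get("sim") or {}))
        cfg = AnalysisConfig(**(doc.get("analysis") or {}))
    except TypeError as exc:  # unknown key inside a section
        raise ConfigurationError(str(exc)) from exc
    return design, cfg
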