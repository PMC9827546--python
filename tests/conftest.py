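"""Shared fixtures: small synthetic studies and the seed-swept default runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import mitoburst as mb
from mitoburst.config import AnalysisConfig
from mitoburst.kinetics import classify_reactivation, cumulative_curves
from mitoburst.pipeline import default_synthetic_config
from mitoburst.prep import compute_trajectories, select_tss
from mitoburst.proximity import classify_bookmarked, distance_stratified_fisher
from mitoburst.response import classify_response, de_test

RECOVERY_SEEDS = tuple(range(1, 11))


@pytest.fixture(scope="session")
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_sim():
    """A 300-gene synthetic study shared across read-only tests."""
    return mb.simulate_run(n_genes=300, seed=7)


def run_default_study(seed: int, n_genes: int = 2_000) -> dict:
    """One full pass of the default study conditions for one seed.

    Returns every quantity the recovery and proximity checks need, so the
    expensive simulation happens once per seed.
    """
    sim = mb.simulate_run(n_genes=n_genes, seed=seed)
    cfg = default_synthetic_config(n_genes)
    curated = {p.gene_id for p in sim.programs}
    kept = mb.filter_genes(sim.expression, sim.sample_sheet, cfg, curated)
    expr_f = sim.expression.loc[kept]
    traj = compute_trajectories(expr_f, sim.sample_sheet, cfg)
    classes = classify_reactivation(traj, cfg)
    curves = cumulative_curves(traj, classes)
    truth = sim.truth.set_index("gene_id").loc[kept]

    de = de_test(expr_f, sim.sample_sheet, cfg)
    rc = classify_response(de, cfg)
    concordant = rc[rc["timing"] != "discordant"]
    mapping = {r.gene_id: f"{r.timing}_{r.direction}" for r in concordant.itertuples()}
    resp_groups = pd.DataFrame({"gene_id": kept,
                                "class": [mapping.get(g, "no_response") for g in kept]})
    tss = select_tss(sim.genes, sim.evidence)
    tss = tss[tss["gene_id"].isin(kept)].reset_index(drop=True)
    labels = classify_bookmarked(sim.peaks_interphase, sim.peaks_mitotic)
    track = distance_stratified_fisher(resp_groups, sim.peaks_interphase, labels, tss, cfg)
    return {"sim": sim, "cfg": cfg, "kept": kept, "traj": traj, "classes": classes,
            "curves": curves, "truth": truth, "response": rc, "track": track}


@pytest.fixture(scope="session")
def default_runs() -> dict[int, dict]:
    """Default-condition studies over the ten recovery seeds."""
    return {seed: run_default_study(seed) for seed in RECOVERY_SEEDS}
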