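"""Annotation rules, expression filter, and trajectory arithmetic."""

import numpy as np
import pandas as pd
import pytest

from mitoburst import io as mio
from mitoburst.config import AnalysisConfig, ConfigurationError
from mitoburst.prep import (PREMRNA_SUFFIX, augment_gtf_with_premrna,
                            compute_sample_lfc, compute_trajectories,
                            filter_genes, rank_genes, select_tss)


def make_gene(gene_id="gA", chrom="chr1", strand="+", spans=((1000, 2000),)):
    transcripts = [mio.Transcript(f"{gene_id}.t{i+1}", s, e, exons=[(s, e)])
                   for i, (s, e) in enumerate(spans)]
    return mio.Gene(gene_id, chrom, strand, transcripts)


# ---------------------------------------------------------------------------
# pre-mRNA augmentation
# ---------------------------------------------------------------------------

class TestAugment:
    def test_single_transcript_premrna_matches_its_span(self):
        (g,) = augment_gtf_with_premrna([make_gene()])
        pre = g.transcripts[-1]
        assert pre.transcript_id == "gA" + PREMRNA_SUFFIX
        assert (pre.start, pre.end) == (1000, 2000)
        assert pre.exons == [(1000, 2000)]

    def test_longest_span_wins_not_the_union(self):
        (g,) = augment_gtf_with_premrna([make_gene(spans=((100, 500), (150, 800)))])
        pre = g.transcripts[-1]
        assert (pre.start, pre.end) == (150, 800)  # span 650 beats 400

    def test_union_mode_spans_all_isoforms(self):
        (g,) = augment_gtf_with_premrna([make_gene(spans=((100, 500), (150, 800)))],
                                        union=True)
        assert (g.transcripts[-1].start, g.transcripts[-1].end) == (100, 800)

    def test_output_has_exactly_n_more_transcripts(self):
        genes = [make_gene(f"g{i}", spans=((0, 100 * (i + 2)),)) for i in range(7)]
        before = sum(len(g.transcripts) for g in genes)
        after = sum(len(g.transcripts) for g in augment_gtf_with_premrna(genes))
        assert after == before + 7

    def test_exonless_transcripts_warn_and_do_not_contribute(self, caplog):
        g = make_gene(spans=((100, 500),))
        g.transcripts.append(mio.Transcript("gA.bad", 0, 9000, exons=[]))
        (out,) = augment_gtf_with_premrna([g])
        pre = out.transcripts[-1]
        assert (pre.start, pre.end) == (100, 500)  # exonless span ignored
        assert any("no exons" in r.message for r in caplog.records)

    def test_originals_untouched(self):
        genes = [make_gene()]
        augment_gtf_with_premrna(genes)
        assert len(genes[0].transcripts) == 1

    def test_gtf_round_trip_preserves_intervals(self, tmp_path):
        genes = augment_gtf_with_premrna(
            [make_gene("gA", spans=((100, 500), (150, 800))),
             make_gene("gB", strand="-", spans=((2000, 9000),))])
        mio.write_gtf(genes, tmp_path / "x.gtf")
        back = {g.gene_id: g for g in mio.read_gtf(tmp_path / "x.gtf")}
        for g in genes:
            for t, t2 in zip(g.transcripts, sorted(back[g.gene_id].transcripts,
                                                   key=lambda t: t.transcript_id)):
                pass
        assert {(t.transcript_id, t.start, t.end) for g in genes for t in g.transcripts} \
            == {(t.transcript_id, t.start, t.end) for g in back.values() for t in g.transcripts}


# ---------------------------------------------------------------------------
# TSS selection
# ---------------------------------------------------------------------------

def ev_row(gene_id, pos, scores, chrom="chr1", strand="+"):
    return {"gene_id": gene_id, "transcript_id": f"{gene_id}.t", "chrom": chrom,
            "pos": pos, "strand": strand,
            "rnapii": scores[0], "h3k4me3": scores[1], "dnase": scores[2]}


class TestSelectTss:
    def test_single_candidate_is_chosen(self):
        tss = select_tss([make_gene()], pd.DataFrame([ev_row("gA", 1000, (0.5, 0.2, 0.1))]))
        assert tss.iloc[0]["pos"] == 1000

    def test_dominant_scores_win(self):
        ev = pd.DataFrame([ev_row("gA", 1000, (1, 1, 1)), ev_row("gA", 1500, (0, 0, 0))])
        tss = select_tss([make_gene()], ev)
        assert tss.iloc[0]["pos"] == 1000

    def test_exact_tie_on_minus_strand_goes_five_prime(self):
        ev = pd.DataFrame([ev_row("gA", 100, (1, 0, 0), strand="-"),
                           ev_row("gA", 200, (1, 0, 0), strand="-")])
        tss = select_tss([make_gene(strand="-")], ev)
        assert tss.iloc[0]["pos"] == 200  # 5'-most on the minus strand

    def test_gene_without_candidates_excluded_and_logged(self, caplog):
        tss = select_tss([make_gene("gA"), make_gene("gB")],
                         pd.DataFrame([ev_row("gA", 1000, (1, 1, 1))]))
        assert tss["gene_id"].tolist() == ["gA"]
        assert any("gB" in r.message for r in caplog.records)

    def test_rescaling_makes_scores_commensurate(self):
        # after min-max rescaling the totals are 1.0 (strong on one mark)
        # vs 0.4+0.4+0.4 = 1.2 (balanced): the balanced candidate wins even
        # though its raw sum (400.8) dwarfs nothing on the raw RNAPII scale
        ev = pd.DataFrame([ev_row("gA", 1000, (1000.0, 0.0, 0.0)),
                           ev_row("gA", 1500, (400.0, 0.4, 0.4)),
                           ev_row("gB", 5000, (0.0, 1.0, 1.0))])
        tss = select_tss([make_gene("gA"), make_gene("gB", spans=((4000, 6000),))], ev)
        assert tss.set_index("gene_id").loc["gA", "pos"] == 1500


# ---------------------------------------------------------------------------
# expression filter
# ---------------------------------------------------------------------------

def toy_sheet():
    rows = [("A1", "untreated", "asynchronous", np.nan, "r1"),
            ("A2", "untreated", "asynchronous", np.nan, "r2"),
            ("M1", "untreated", "mitotic", np.nan, "r1"),
            ("M2", "untreated", "mitotic", np.nan, "r2"),
            ("T20a", "untreated", "release", 20.0, "r1"),
            ("T20b", "untreated", "release", 20.0, "r2"),
            ("T90a", "untreated", "release", 90.0, "r1"),
            ("T90b", "untreated", "release", 90.0, "r2")]
    return pd.DataFrame(rows, columns=["sample_id", "condition", "state", "time_min", "replicate"])


class TestFilterGenes:
    @pytest.mark.parametrize("async_vals,release_vals,expected", [
        ((0.6, 0.6), (0.0, 0.0, 0.0, 0.0), True),    # asynchronous clause
        ((0.1, 0.1), (0.6, 0.7, 0.0, 0.0), True),    # >=2 release samples clause
        ((0.5, 0.5), (5.0, 0.0, 0.0, 0.0), False),   # strict >, single qualifying sample
        ((0.5, 0.5), (0.5, 0.5, 0.5, 0.5), False),   # boundary exactly at threshold
    ])
    def test_filter_rule_enumeration(self, async_vals, release_vals, expected, cfg):
        expr = pd.DataFrame([[*async_vals, 1.0, 1.0, *release_vals]],
                            index=["g1"], columns=toy_sheet()["sample_id"])
        expr.index.name = "gene_id"
        kept = filter_genes(expr, toy_sheet(), cfg, {"g1"})
        assert (kept == ["g1"]) is expected

    def test_uncurated_gene_dropped_even_if_expressed(self, cfg):
        expr = pd.DataFrame([[9.0] * 8], index=["g1"], columns=toy_sheet()["sample_id"])
        assert filter_genes(expr, toy_sheet(), cfg, {"other"}) == []

    def test_empty_curated_set_is_a_configuration_error(self, cfg):
        expr = pd.DataFrame([[9.0] * 8], index=["g1"], columns=toy_sheet()["sample_id"])
        with pytest.raises(ConfigurationError):
            filter_genes(expr, toy_sheet(), cfg, set())

    def test_idempotent_and_column_order_independent(self, cfg):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.exponential(1.0, size=(30, 8)),
                            index=[f"g{i}" for i in range(30)],
                            columns=toy_sheet()["sample_id"])
        curated = {f"g{i}" for i in range(0, 30, 2)}
        kept = filter_genes(expr, toy_sheet(), cfg, curated)
        assert filter_genes(expr.loc[kept], toy_sheet(), cfg, curated) == kept
        shuffled = expr[list(expr.columns[::-1])]
        assert filter_genes(shuffled, toy_sheet(), cfg, curated) == kept


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

class TestTrajectories:
    def test_identical_tpm_gives_zero_lfc_everywhere(self, cfg):
        expr = pd.DataFrame([[2.0] * 8], index=["g1"], columns=toy_sheet()["sample_id"])
        traj = compute_trajectories(expr, toy_sheet(), cfg)
        assert traj.table.loc["g1", ["lfc_20", "lfc_90", "log2fc_async"]].tolist() == [0, 0, 0]

    def test_replicate_averaging_hand_arithmetic(self, cfg):
        # rep1: t=3 vs M=1 -> +1; rep2: t=1 vs M=3 -> -1; mean 0 (pc=1)
        expr = pd.DataFrame([[1, 1, 1.0, 3.0, 3.0, 1.0, 1, 3]],
                            index=["g1"], columns=toy_sheet()["sample_id"])
        traj = compute_trajectories(expr, toy_sheet(), cfg)
        assert traj.table.loc["g1", "lfc_20"] == pytest.approx(0.0)

    def test_pseudocount_bounds_zero_mitotic_fold_change(self, cfg):
        # mitotic 0, release 7, pc 1 -> log2(8/1) = 3
        expr = pd.DataFrame([[0, 0, 0.0, 0.0, 7.0, 7.0, 7, 7]],
                            index=["g1"], columns=toy_sheet()["sample_id"])
        traj = compute_trajectories(expr, toy_sheet(), cfg)
        assert traj.table.loc["g1", "lfc_20"] == pytest.approx(3.0)

    def test_unpairable_sample_is_a_hard_error_naming_it(self, cfg):
        sheet = toy_sheet()
        sheet = sheet[sheet["sample_id"] != "M2"]  # two mitotic pools -> one left... drop to force ambiguity
        sheet.loc[sheet["sample_id"] == "T20b", "replicate"] = "r9"
        expr = pd.DataFrame([[1.0] * len(sheet)], index=["g1"],
                            columns=sheet["sample_id"])
        # one mitotic pool remains: every orphan pairs to it -> no error
        compute_trajectories(expr, sheet, cfg)
        sheet2 = toy_sheet()
        sheet2.loc[sheet2["sample_id"] == "T20b", "replicate"] = "r9"
        expr2 = pd.DataFrame([[1.0] * 8], index=["g1"], columns=sheet2["sample_id"])
        with pytest.raises(ValueError, match="T20b"):
            compute_trajectories(expr2, sheet2, cfg)

    def test_zscore_vector_standardized(self, small_sim, cfg):
        traj = compute_trajectories(small_sim.expression, small_sim.sample_sheet, cfg)
        z = traj.zscores
        nonconst = z.abs().sum(axis=1) > 0
        assert np.allclose(z[nonconst].mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(z[nonconst].std(axis=1, ddof=0), 1.0, atol=1e-9)

    def test_library_rescaling_shifts_lfc_by_log2c_in_small_pc_limit(self):
        cfg0 = AnalysisConfig(pseudocount_tpm=1e-9)
        expr = pd.DataFrame([[4, 4, 4, 4, 6.0, 6.0, 2, 2]],
                            index=["g1"], columns=toy_sheet()["sample_id"])
        base = compute_trajectories(expr, toy_sheet(), cfg0).table.loc["g1", "lfc_20"]
        expr2 = expr.copy()
        expr2["T20a"] *= 8.0
        expr2["T20b"] *= 8.0
        shifted = compute_trajectories(expr2, toy_sheet(), cfg0).table.loc["g1", "lfc_20"]
        assert shifted - base == pytest.approx(3.0, abs=1e-6)

    def test_mean_fc_20_90_is_the_arithmetic_mean(self, cfg):
        expr = pd.DataFrame([[1, 1, 1.0, 1.0, 3.0, 3.0, 7, 7]],
                            index=["g1"], columns=toy_sheet()["sample_id"])
        traj = compute_trajectories(expr, toy_sheet(), cfg)
        t = traj.table.loc["g1"]
        assert t["mean_fc_20_90"] == pytest.approx((t["lfc_20"] + t["lfc_90"]) / 2)


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

class TestRanking:
    def _traj_from_means(self, means: dict):
        from mitoburst.prep import TrajectorySet
        tab = pd.DataFrame({"mean_fc_20_90": pd.Series(means)})
        return TrajectorySet(timepoints=(), table=tab, zscores=pd.DataFrame(index=tab.index))

    def test_descending_order(self):
        assert rank_genes(self._traj_from_means({"a": 0.5, "b": 2.0})) == ["b", "a"]

    def test_ties_break_lexicographically(self):
        assert rank_genes(self._traj_from_means({"z": 1.0, "a": 1.0, "m": 1.0})) == ["a", "m", "z"]

    def test_planted_fast_onsets_rank_above_late_onsets_at_zero_noise(self, cfg):
        from mitoburst.config import SimDesign
        from mitoburst.simulate import GeneProgram, generate_expression
        progs = [GeneProgram("early", "fast_burst", 20, 8, np.inf, 10, 2),
                 GeneProgram("late", "late", 90, 8, np.inf, 10, 2)]
        expr, sheet = generate_expression(progs, SimDesign(), noise_sd_log2=0.0, seed=0)
        traj = compute_trajectories(expr, sheet, cfg)
        assert rank_genes(traj) == ["early", "late"]
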