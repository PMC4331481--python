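"""The generator's planted structure must be recoverable and deterministic."""

import numpy as np
import pandas as pd
import pytest

from tdmrlink import simulate as sim
from tdmrlink.model import DELTA_E_THRESHOLD


class TestGenomeAndGenes:
    def test_byte_identical_given_seed(self):
        cfg = sim.SimConfig(n_genes=30, n_dmrs=40, seed=5)
        g1, genes1 = sim.generate_genome_and_genes(cfg)
        g2, genes2 = sim.generate_genome_and_genes(cfg)
        assert g1 == g2
        assert genes1 == genes2

    def test_fixed_gene_length(self):
        cfg = sim.SimConfig(n_genes=20, n_dmrs=20, gene_len_range=(1000, 1000), seed=1)
        genes, _ = sim.generate_genes(cfg)
        assert all(g.interval.length == 1000 for g in genes)

    def test_strand_alternation(self):
        cfg = sim.SimConfig(n_genes=40, n_dmrs=40, seed=1)
        genes, _ = sim.generate_genes(cfg)
        n_minus = sum(g.strand == "-" for g in genes)
        assert n_minus == 20

    def test_genes_do_not_overlap(self):
        cfg = sim.SimConfig(n_genes=50, n_dmrs=50, seed=3)
        genes, span = sim.generate_genes(cfg)
        prev_end = 0
        for g in sorted(genes, key=lambda g: g.interval.start):
            assert g.interval.start >= prev_end
            prev_end = g.interval.end
        assert prev_end <= span

    def test_layout_independent_of_sequence_stream(self):
        cfg = sim.SimConfig(n_genes=25, n_dmrs=30, seed=9)
        genes_only, _ = sim.generate_genes(cfg)
        _, genes_with_seq = sim.generate_genome_and_genes(cfg)
        assert genes_only == genes_with_seq


class TestMethylationExpression:
    def test_all_pairs_concordant_when_frac_positive_one(self):
        cfg = sim.SimConfig(n_genes=100, n_dmrs=120, seed=2, frac_positive=1.0,
                            frac_subthreshold=0.0)
        genes, _ = sim.generate_genes(cfg)
        _, _, truth = sim.generate_methylation_expression(cfg, genes)
        assert (truth["planted_relation"] == "positive").all()
        assert (np.sign(truth["delta_m"]) == np.sign(truth["true_delta_e"])).all()

    def test_planted_positive_count_near_binomial_expectation(self):
        cfg = sim.SimConfig(n_genes=1800, n_dmrs=2500, seed=4, frac_positive=0.34,
                            coherence_bias=0.0, frac_subthreshold=0.0)
        genes, _ = sim.generate_genes(cfg)
        _, _, truth = sim.generate_methylation_expression(cfg, genes)
        n_pos = (truth["planted_relation"] == "positive").sum()
        # binomial(2500, 0.34): mean 850, sd ~23.7; allow 4 sd
        assert abs(n_pos - 850) < 4 * np.sqrt(2500 * 0.34 * 0.66)

    def test_zero_replicate_noise_gives_exact_delta_e(self):
        cfg = sim.SimConfig(n_genes=80, n_dmrs=90, seed=6, rep_noise_sd=0.0)
        genes, _ = sim.generate_genes(cfg)
        _, exprs, truth = sim.generate_methylation_expression(cfg, genes)
        observed = {r.gene_id: r.delta_e for r in exprs}
        for row in truth.itertuples(index=False):
            assert observed[row.gene_id] == pytest.approx(row.true_delta_e, abs=1e-9)

    def test_informative_pairs_above_threshold(self):
        cfg = sim.SimConfig(n_genes=120, n_dmrs=150, seed=7)
        genes, _ = sim.generate_genes(cfg)
        _, _, truth = sim.generate_methylation_expression(cfg, genes)
        informative = truth[truth["planted_class"] != "subthreshold"]
        sub = truth[truth["planted_class"] == "subthreshold"]
        assert (informative["true_delta_e"].abs() > DELTA_E_THRESHOLD).all()
        assert (sub["true_delta_e"].abs() < DELTA_E_THRESHOLD).all()
        assert len(sub) > 0

    def test_delta_m_floor_and_level_bounds(self, small_study):
        dmrs = small_study["dmrs"]
        for d in dmrs:
            assert abs(d.delta_m) >= small_study["config"].delta_m_floor - 1e-12
            assert 0.0 <= d.m_tissue1 <= 1.0
            assert 0.0 <= d.m_tissue2 <= 1.0

    def test_dmrs_within_host_gene_window(self, small_study):
        genes = {g.gene_id: g for g in small_study["genes"]}
        dmr_by_id = {d.dmr_id: d for d in small_study["dmrs"]}
        for row in small_study["truth"].itertuples(index=False):
            w = genes[row.gene_id].regulatory_window(small_study["config"].upstream_bp)
            iv = dmr_by_id[row.dmr_id].interval
            assert w.start <= iv.start and iv.end <= w.end

    def test_infeasible_dmr_count_raises(self):
        cfg = sim.SimConfig(n_genes=3, n_dmrs=50, seed=1)
        genes, _ = sim.generate_genes(cfg)
        with pytest.raises(sim.SimulationError):
            sim.generate_methylation_expression(cfg, genes)


class TestDHSTracks:
    def test_zero_overlap_fraction_means_no_overlap(self, small_study):
        cfg = sim.SimConfig(n_genes=250, n_dmrs=320, seed=11,
                            dhs_dmr_overlap_frac=0.0)
        p1, p2, truth = sim.generate_dhs_tracks(cfg, small_study["dmrs"],
                                                small_study["span"])
        assert truth["planted_overlap_frac"] == 0.0
        peaks = sorted({(p.start, p.end) for p in p1 + p2})
        for d in small_study["dmrs"]:
            for s, e in peaks:
                assert not (d.interval.start < e and s < d.interval.end)

    def test_planted_overlap_fraction_exact(self, small_study):
        cfg = small_study["config"]
        p1, p2, truth = sim.generate_dhs_tracks(cfg, small_study["dmrs"],
                                                small_study["span"])
        peaks = sorted({(p.start, p.end) for p in p1 + p2})
        n_hit = 0
        for d in small_study["dmrs"]:
            n_hit += any(d.interval.start < e and s < d.interval.end for s, e in peaks)
        assert n_hit / len(small_study["dmrs"]) == pytest.approx(
            truth["planted_overlap_frac"], abs=1e-12
        )

    def test_all_peaks_shared_when_share_is_one(self, small_study):
        cfg = sim.SimConfig(n_genes=250, n_dmrs=320, seed=11, dhs_shared_frac=1.0)
        p1, p2, _ = sim.generate_dhs_tracks(cfg, small_study["dmrs"],
                                            small_study["span"])
        assert {(p.start, p.end) for p in p1} == {(p.start, p.end) for p in p2}


class TestPlantMotifs:
    def test_rate_zero_leaves_sequences_unchanged(self):
        cfg = sim.SimConfig(seed=1, planted_motifs_pos=(("ACGTAC", 0.0),))
        seqs = {"positive": ["A" * 50, "C" * 40]}
        out, log = sim.plant_motifs(cfg, seqs)
        assert out == seqs
        assert log.empty

    def test_rate_one_inserts_in_every_sequence(self):
        cfg = sim.SimConfig(seed=1, planted_motifs_pos=(("ACGTAC", 1.0),))
        seqs = {"positive": ["A" * 60] * 100}
        out, log = sim.plant_motifs(cfg, seqs)
        assert len(log) == 100
        assert sum(s.count("ACGTAC") for s in out["positive"]) >= 100
        assert all(len(s) == 60 for s in out["positive"])  # overwrite keeps length

    def test_only_matching_class_mutated(self):
        cfg = sim.SimConfig(seed=1, planted_motifs_pos=(("ACGTAC", 1.0),))
        seqs = {"positive": ["A" * 60], "negative": ["A" * 60]}
        out, _ = sim.plant_motifs(cfg, seqs)
        assert out["negative"] == ["A" * 60]

    def test_invalid_motif_alphabet_rejected(self):
        cfg = sim.SimConfig(seed=1, planted_motifs_pos=(("ACGTAN", 1.0),))
        with pytest.raises(ValueError):
            sim.plant_motifs(cfg, {"positive": ["A" * 30]})


class TestConservation:
    def _scores(self, shift_pos, shift_neg, study):
        cfg = sim.SimConfig(n_genes=250, n_dmrs=320, seed=11,
                            cons_shift_positive=shift_pos,
                            cons_shift_negative=shift_neg, cons_shift_exon=0.0)
        classes = dict(zip(study["truth"]["dmr_id"], study["truth"]["planted_class"]))
        return sim.generate_conservation(cfg, study["dmrs"], classes,
                                         study["genome"], study["genes"],
                                         n_background=500)

    def test_scores_clipped_to_unit_interval(self, small_study):
        df = self._scores(0.3, 0.1, small_study)
        assert df["score"].between(0, 1).all()

    def test_class_shift_moves_the_mean(self, small_study):
        df = self._scores(0.3, 0.0, small_study)
        means = df.groupby("class")["score"].mean()
        assert means["positive"] > means["negative"] + 0.1
        assert means["negative"] == pytest.approx(means["background"], abs=0.05)

    def test_zero_shift_classes_indistinguishable(self, small_study):
        from scipy.stats import ks_2samp

        df = self._scores(0.0, 0.0, small_study)
        pos = df.loc[df["class"] == "positive", "score"]
        neg = df.loc[df["class"] == "negative", "score"]
        assert ks_2samp(pos, neg).pvalue > 0.01


def test_random_sequences_lengths_and_determinism():
    a = sim.random_sequences([10, 20, 30], seed=3)
    b = sim.random_sequences([10, 20, 30], seed=3)
    assert a == b
    assert [len(s) for s in a] == [10, 20, 30]
    assert set("".join(a)) <= set("ACGT")
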