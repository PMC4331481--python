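"""DMR-to-gene assignment, sign classification and the shuffle null."""

import math

import numpy as np
import pandas as pd
import pytest

from tdmrlink import association as assoc
from tdmrlink.model import (
    AssociationPair,
    DELTA_E_THRESHOLD,
    ExpressionRecord,
    GeneModel,
    GenomicInterval,
    TDMR,
)


def _gene(gene_id, chrom, start, end, strand):
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand))


def _dmr(dmr_id, chrom, start, end, dm=0.3):
    return TDMR(dmr_id, GenomicInterval(chrom, start, end), 0.5 + dm / 2, 0.5 - dm / 2)


def _expr(gene_id, de):
    return ExpressionRecord(gene_id, (5.0 + de,), (5.0,))


class TestAssignProximal:
    def test_upstream_dmr_within_window_pairs(self):
        # a DMR ~3 kb upstream of a '+' TSS is proximal
        gene = _gene("g1", "chr1", 10000, 20000, "+")
        expr = {"g1": _expr("g1", 1.0)}
        pairs = assoc.assign_proximal([_dmr("d1", "chr1", 7000, 7200)], [gene], expr)
        assert [(p.dmr_id, p.gene_id, p.proximity) for p in pairs] == [
            ("d1", "g1", "proximal")
        ]

    def test_dmr_beyond_4kb_upstream_not_paired(self):
        gene = _gene("g1", "chr1", 10000, 20000, "+")
        expr = {"g1": _expr("g1", 1.0)}
        assert assoc.assign_proximal([_dmr("d1", "chr1", 5000, 5500)], [gene], expr) == []

    def test_minus_strand_upstream_is_rightward(self):
        # '-' gene [1000,2000): window covers [1000, 6000)
        gene = _gene("g1", "chr1", 1000, 2000, "-")
        expr = {"g1": _expr("g1", 1.0)}
        pairs = assoc.assign_proximal([_dmr("d1", "chr1", 2500, 2600)], [gene], expr)
        assert len(pairs) == 1
        assert assoc.assign_proximal([_dmr("d2", "chr1", 500, 900)], [gene], expr) == []

    def test_dmr_overlapping_k_windows_yields_k_pairs(self):
        genes = [
            _gene("gA", "chr1", 10000, 12000, "+"),
            _gene("gB", "chr1", 13000, 15000, "+"),
        ]
        expr = {"gA": _expr("gA", 1.0), "gB": _expr("gB", -1.0)}
        # overlaps gA's body end and gB's upstream window
        pairs = assoc.assign_proximal([_dmr("d1", "chr1", 11500, 12500)], genes, expr)
        assert sorted(p.gene_id for p in pairs) == ["gA", "gB"]

    def test_gene_without_expression_skipped(self):
        gene = _gene("g1", "chr1", 10000, 20000, "+")
        assert assoc.assign_proximal([_dmr("d1", "chr1", 10500, 10900)], [gene], {}) == []

    def test_reflection_and_strand_flip_invariance(self, small_study):
        """Mirroring the genome and flipping all strands must preserve pairs."""
        genes, dmrs = small_study["genes"], small_study["dmrs"]
        expr = {r.gene_id: r for r in small_study["exprs"]}
        span = small_study["span"]
        flip = {"+": "-", "-": "+"}
        genes_r = [
            GeneModel(
                g.gene_id,
                GenomicInterval(g.interval.chrom, span - g.interval.end,
                                span - g.interval.start, flip[g.strand]),
            )
            for g in genes
        ]
        dmrs_r = [
            TDMR(d.dmr_id,
                 GenomicInterval(d.interval.chrom, span - d.interval.end,
                                 span - d.interval.start),
                 d.m_tissue1, d.m_tissue2)
            for d in dmrs
        ]
        orig = {(p.dmr_id, p.gene_id) for p in assoc.assign_proximal(dmrs, genes, expr)}
        refl = {(p.dmr_id, p.gene_id) for p in assoc.assign_proximal(dmrs_r, genes_r, expr)}
        assert orig == refl and len(orig) > 0


class TestAssignDistal:
    def _map(self, rows):
        return pd.DataFrame(
            rows, columns=["enhancer_chrom", "enhancer_start", "enhancer_end",
                           "target_gene_id"]
        )

    def test_single_enhancer_single_target(self):
        emap = self._map([("chr1", 100000, 101000, "gX")])
        expr = {"gX": _expr("gX", 1.0)}
        pairs = assoc.assign_distal([_dmr("d1", "chr1", 100400, 100600)], emap, expr)
        assert [(p.gene_id, p.proximity) for p in pairs] == [("gX", "distal")]

    def test_two_enhancers_three_targets_three_pairs(self):
        emap = self._map(
            [("chr1", 100000, 101000, "gX"), ("chr1", 100000, 101000, "gY"),
             ("chr1", 100500, 102000, "gZ")]
        )
        expr = {g: _expr(g, 1.0) for g in ("gX", "gY", "gZ")}
        pairs = assoc.assign_distal([_dmr("d1", "chr1", 100400, 100600)], emap, expr)
        assert sorted(p.gene_id for p in pairs) == ["gX", "gY", "gZ"]

    def test_no_overlap_no_pairs(self):
        emap = self._map([("chr1", 100000, 101000, "gX")])
        expr = {"gX": _expr("gX", 1.0)}
        assert assoc.assign_distal([_dmr("d1", "chr1", 200000, 200100)], emap, expr) == []

    def test_existing_proximal_pair_not_duplicated(self):
        emap = self._map([("chr1", 100000, 101000, "gX")])
        expr = {"gX": _expr("gX", 1.0)}
        existing = [AssociationPair("d1", "gX", "proximal", 0.3, 1.0)]
        assert assoc.assign_distal(
            [_dmr("d1", "chr1", 100400, 100600)], emap, expr, existing_pairs=existing
        ) == []

    def test_missing_target_dropped_with_warning(self, caplog):
        emap = self._map([("chr1", 100000, 101000, "gMissing")])
        with caplog.at_level("WARNING", logger="tdmrlink"):
            pairs = assoc.assign_distal([_dmr("d1", "chr1", 100400, 100600)], emap, {})
        assert pairs == []
        assert "missing" in caplog.text


class TestClassifySign:
    @pytest.mark.parametrize(
        "dm,de,expected",
        [
            (0.2, 1.0, "positive"),
            (0.2, -1.0, "negative"),
            (-0.2, -1.0, "positive"),
            (0.2, math.log2(1.2), "excluded"),  # below the 25% fold-change bar
            (0.0, 1.0, "excluded"),
        ],
    )
    def test_sign_rules(self, dm, de, expected):
        pair = AssociationPair("d", "g", "proximal", dm, de)
        assoc.classify_sign([pair])
        assert pair.sign_class == expected

    def test_fractions_sum_to_one_over_non_excluded(self):
        pairs = [
            AssociationPair(f"d{i}", f"g{i}", "proximal", dm, de)
            for i, (dm, de) in enumerate(
                [(0.3, 1.0), (0.3, -1.0), (-0.2, 1.0), (0.1, 0.1)]
            )
        ]
        [s] = assoc.classify_sign(pairs).values()
        assert s.n_excluded == 1
        assert s.positive_pair_fraction + s.negative_pair_fraction == pytest.approx(1.0)

    def test_unique_dmr_majority_vote_with_tie_drop(self):
        pairs = [
            AssociationPair("d1", "gA", "proximal", 0.3, 1.0),   # positive
            AssociationPair("d1", "gB", "proximal", 0.3, 2.0),   # positive
            AssociationPair("d1", "gC", "proximal", 0.3, -1.0),  # negative
            AssociationPair("d2", "gA", "proximal", 0.3, 1.0),   # positive
            AssociationPair("d3", "gA", "proximal", -0.3, 1.0),  # negative
            AssociationPair("d3", "gB", "proximal", -0.3, -2.0),  # positive -> tie
        ]
        [s] = assoc.classify_sign(pairs).values()
        assert (s.n_positive_dmrs, s.n_negative_dmrs, s.n_tied_dmrs) == (2, 0, 1)


class TestShuffleExpectedSignFractions:
    def _pairs(self, dm_signs, de_vals):
        return [
            AssociationPair(f"d{i}", f"g{i}", "proximal", 0.3 * s, de)
            for i, (s, de) in enumerate(zip(dm_signs, de_vals))
        ]

    def test_converges_to_closed_form(self):
        # marginals p = 0.7 (delta_m positive), q = 0.6 (delta_e positive):
        # expected positive fraction = p*q + (1-p)*(1-q) = 0.54
        dm = [1] * 70 + [-1] * 30
        de = [1.0] * 60 + [-1.0] * 40
        res = assoc.shuffle_expected_sign_fractions(
            self._pairs(dm, de), n_shuffles=4000, seed=1
        )
        assert res.expected_positive == pytest.approx(0.54, abs=0.005)

    def test_all_concordant_gives_one(self):
        res = assoc.shuffle_expected_sign_fractions(
            self._pairs([1] * 10, [1.0] * 10), n_shuffles=100, seed=0
        )
        assert res.expected_positive == 1.0

    def test_deterministic_given_seed(self):
        pairs = self._pairs([1, -1] * 20, [1.0, -1.0, 2.0, -2.0] * 10)
        r1 = assoc.shuffle_expected_sign_fractions(pairs, n_shuffles=500, seed=42)
        r2 = assoc.shuffle_expected_sign_fractions(pairs, n_shuffles=500, seed=42)
        assert r1 == r2

    def test_all_excluded_raises(self):
        pairs = self._pairs([1, -1], [0.1, -0.1])
        with pytest.raises(ValueError):
            assoc.shuffle_expected_sign_fractions(pairs, n_shuffles=10, seed=0)


class TestGoEnrichment:
    def _g2t(self, mapping):
        rows = [
            {"gene_id": g, "term_id": t, "term_name": t.lower()}
            for t, genes in mapping.items()
            for g in genes
        ]
        return pd.DataFrame(rows)

    def test_term_in_every_background_gene(self):
        background = [f"g{i}" for i in range(20)]
        g2t = self._g2t({"T1": background})
        [r] = assoc.go_enrichment(background[:10], background, g2t)
        assert r.ratio == pytest.approx(1.0)
        assert r.p == pytest.approx(1.0)

    def test_exact_hypergeometric_value(self):
        background = [f"g{i}" for i in range(20)]
        g2t = self._g2t({"T1": background[:5]})
        [r] = assoc.go_enrichment(background[:10], background, g2t)
        assert (r.k, r.n, r.K, r.N) == (5, 10, 5, 20)
        assert r.p == pytest.approx(3003 / 184756, abs=1e-12)

    def test_bonferroni_over_tested_terms_only(self):
        background = [f"g{i}" for i in range(30)]
        g2t = self._g2t(
            {"T1": background[:6], "T2": background[5:12], "Tiny": background[:2]}
        )
        res = assoc.go_enrichment(background[:10], background, g2t, min_term_genes=5)
        assert len(res) == 2  # "Tiny" below min_term_genes
        for r in res:
            assert r.p_corrected == pytest.approx(min(1.0, r.p * 2))

    def test_empty_gene_set(self):
        assert assoc.go_enrichment([], ["g1"], self._g2t({"T": ["g1"]})) == []

    def test_gene_set_outside_background_rejected(self):
        with pytest.raises(ValueError):
            assoc.go_enrichment(["gX"], ["g1"], self._g2t({"T": ["g1"]}))
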