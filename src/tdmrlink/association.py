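"""Assigning T-DMRs to genes and classifying the methylation–expression sign.

A *proximal* pair links a DMR to any gene whose strand-aware regulatory
window (4 kb upstream of the TSS through the transcription end) it overlaps
by at least 1 bp.  A *distal* pair links a DMR to a gene through an
enhancer–promoter map.  Each pair is classified ``positive`` when ΔM and ΔE
share a sign, ``negative`` when they differ, and ``excluded`` when
|ΔE| <= log2(1.25) or either difference is exactly zero.

The observed positive/negative split is compared with a permutation null
that shuffles ΔM across pairs while holding each gene's ΔE fixed.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import logger, read_enhancer_map
from .model import (
    DELTA_E_THRESHOLD,
    AssociationPair,
    EnrichmentResult,
    ExpressionRecord,
    GeneModel,
    GenomicInterval,
    TDMR,
)
from .stats import bonferroni, hypergeom_upper_tail

__all__ = [
    "assign_proximal",
    "assign_distal",
    "classify_sign",
    "SignSummary",
    "shuffle_expected_sign_fractions",
    "go_enrichment",
]


def _window_trees(
    genes: Sequence[GeneModel], upstream_bp: int
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for gene in genes:
        w = gene.regulatory_window(upstream_bp)
        trees[w.chrom].addi(w.start, w.end, gene)
    return dict(trees)


def assign_proximal(
    dmrs: Sequence[TDMR],
    genes: Sequence[GeneModel],
    expression: Mapping[str, ExpressionRecord],
    upstream_bp: int = 4000,
) -> list[AssociationPair]:
    """Pairs for every (DMR, gene window) overlap of >= 1 bp.

    A DMR overlapping k gene windows yields k pairs.  Genes absent from the
    expression table are skipped (counted in the log).
    """
    trees = _window_trees(genes, upstream_bp)
    pairs: list[AssociationPair] = []
    n_missing_expr = 0
    for dmr in dmrs:
        tree = trees.get(dmr.interval.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(dmr.interval.start, dmr.interval.end),
                          key=lambda h: h.data.gene_id):
            gene: GeneModel = hit.data
            rec = expression.get(gene.gene_id)
            if rec is None:
                n_missing_expr += 1
                continue
            pairs.append(
                AssociationPair(
                    dmr_id=dmr.dmr_id,
                    gene_id=gene.gene_id,
                    proximity="proximal",
                    delta_m=dmr.delta_m,
                    delta_e=rec.delta_e,
                )
            )
    if n_missing_expr:
        logger.info("assign_proximal: %d candidate pairs skipped for missing expression",
                    n_missing_expr)
    return pairs


def assign_distal(
    dmrs: Sequence[TDMR],
    enhancer_map: pd.DataFrame | str,
    expression: Mapping[str, ExpressionRecord],
    existing_pairs: Sequence[AssociationPair] = (),
) -> list[AssociationPair]:
    """Pairs for DMRs overlapping mapped enhancers, one per target gene.

    A (DMR, gene) combination already present in ``existing_pairs`` (for
    example, from the proximal pass) is not duplicated.  Enhancer targets
    missing from the expression table are dropped with a warning.
    """
    if isinstance(enhancer_map, str):
        enhancer_map = read_enhancer_map(enhancer_map)
    seen = {(p.dmr_id, p.gene_id) for p in existing_pairs}
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for row in enhancer_map.itertuples(index=False):
        trees[str(row.enhancer_chrom)].addi(
            int(row.enhancer_start), int(row.enhancer_end), str(row.target_gene_id)
        )
    pairs: list[AssociationPair] = []
    n_missing = 0
    for dmr in dmrs:
        tree = trees.get(dmr.interval.chrom)
        if tree is None:
            continue
        targets = sorted({h.data for h in tree.overlap(dmr.interval.start, dmr.interval.end)})
        for gene_id in targets:
            if (dmr.dmr_id, gene_id) in seen:
                continue
            rec = expression.get(gene_id)
            if rec is None:
                n_missing += 1
                continue
            seen.add((dmr.dmr_id, gene_id))
            pairs.append(
                AssociationPair(
                    dmr_id=dmr.dmr_id,
                    gene_id=gene_id,
                    proximity="distal",
                    delta_m=dmr.delta_m,
                    delta_e=rec.delta_e,
                )
            )
    if n_missing:
        logger.warning("assign_distal: %d enhancer targets missing from expression; dropped",
                       n_missing)
    return pairs


@dataclass(frozen=True)
class SignSummary:
    """Positive/negative split for one proximity class.

    Fractions are reported both over pairs and over unique DMRs (majority
    sign per DMR; ties dropped).
    """

    proximity: str
    n_pairs: int
    n_excluded: int
    n_positive_pairs: int
    n_negative_pairs: int
    n_unique_dmrs: int
    n_positive_dmrs: int
    n_negative_dmrs: int
    n_tied_dmrs: int

    @property
    def positive_pair_fraction(self) -> float:
        kept = self.n_positive_pairs + self.n_negative_pairs
        return self.n_positive_pairs / kept if kept else float("nan")

    @property
    def negative_pair_fraction(self) -> float:
        kept = self.n_positive_pairs + self.n_negative_pairs
        return self.n_negative_pairs / kept if kept else float("nan")

    @property
    def positive_dmr_fraction(self) -> float:
        kept = self.n_positive_dmrs + self.n_negative_dmrs
        return self.n_positive_dmrs / kept if kept else float("nan")


def _sign_of(pair: AssociationPair, min_abs_delta_e: float) -> str:
    if abs(pair.delta_e) <= min_abs_delta_e or pair.delta_m == 0 or pair.delta_e == 0:
        return "excluded"
    return "positive" if (pair.delta_m > 0) == (pair.delta_e > 0) else "negative"


def classify_sign(
    pairs: Sequence[AssociationPair],
    min_abs_delta_e: float = DELTA_E_THRESHOLD,
) -> dict[str, SignSummary]:
    """Set ``sign_class`` on every pair (in place) and summarize per proximity."""
    for pair in pairs:
        pair.sign_class = _sign_of(pair, min_abs_delta_e)
    summaries: dict[str, SignSummary] = {}
    for proximity in sorted({p.proximity for p in pairs}):
        sub = [p for p in pairs if p.proximity == proximity]
        kept = [p for p in sub if p.sign_class != "excluded"]
        by_dmr: dict[str, Counter] = defaultdict(Counter)
        for p in kept:
            by_dmr[p.dmr_id][p.sign_class] += 1
        pos_d = neg_d = tied = 0
        for counts in by_dmr.values():
            if counts["positive"] > counts["negative"]:
                pos_d += 1
            elif counts["negative"] > counts["positive"]:
                neg_d += 1
            else:
                tied += 1
        summaries[proximity] = SignSummary(
            proximity=proximity,
            n_pairs=len(sub),
            n_excluded=len(sub) - len(kept),
            n_positive_pairs=sum(p.sign_class == "positive" for p in kept),
            n_negative_pairs=sum(p.sign_class == "negative" for p in kept),
            n_unique_dmrs=len(by_dmr),
            n_positive_dmrs=pos_d,
            n_negative_dmrs=neg_d,
            n_tied_dmrs=tied,
        )
    return summaries


@dataclass(frozen=True)
class ShuffledFractions:
    """Null expectation for the positive/negative split under ΔM shuffling."""

    expected_positive: float
    expected_negative: float
    sd_positive: float
    sd_negative: float
    n_shuffles: int


def shuffle_expected_sign_fractions(
    pairs: Sequence[AssociationPair],
    n_shuffles: int = 10000,
    seed: int = 0,
    min_abs_delta_e: float = DELTA_E_THRESHOLD,
    chunk: int = 512,
) -> ShuffledFractions:
    """Expected sign fractions when ΔM is permuted across pairs.

    ΔE stays attached to its pair, so the |ΔE| filter selects the same pairs
    in every shuffle; only the sign agreement is randomized.
    """
    dm = np.array([p.delta_m for p in pairs], dtype=float)
    de = np.array([p.delta_e for p in pairs], dtype=float)
    keep = (np.abs(de) > min_abs_delta_e) & (de != 0)
    if keep.sum() < 2:
        raise ValueError("need >= 2 pairs passing the ΔE filter")
    rng = np.random.default_rng(seed)
    de_sign = np.sign(de[keep])
    fracs = np.empty(n_shuffles, dtype=float)
    done = 0
    while done < n_shuffles:
        m = min(chunk, n_shuffles - done)
        perm = rng.permuted(np.tile(dm, (m, 1)), axis=1)[:, keep]
        valid = perm != 0
        agree = (np.sign(perm) == de_sign[None, :]) & valid
        fracs[done : done + m] = agree.sum(axis=1) / np.maximum(valid.sum(axis=1), 1)
        done += m
    return ShuffledFractions(
        expected_positive=float(fracs.mean()),
        expected_negative=float(1.0 - fracs.mean()),
        sd_positive=float(fracs.std(ddof=1)),
        sd_negative=float(fracs.std(ddof=1)),
        n_shuffles=n_shuffles,
    )


def go_enrichment(
    gene_set: Sequence[str],
    background: Sequence[str],
    gene2terms: pd.DataFrame,
    min_term_genes: int = 5,
) -> list[EnrichmentResult]:
    """Hypergeometric term enrichment with Bonferroni correction.

    ``gene2terms`` has columns gene_id, term_id, term_name.  Terms with
    fewer than ``min_term_genes`` background genes are not tested; the
    Bonferroni factor is the number of tested terms.  Results are sorted by
    corrected p.
    """
    gene_set_u = set(gene_set)
    background_u = set(background)
    if not gene_set_u <= background_u:
        raise ValueError("gene_set must be a subset of background")
    if not gene_set_u:
        return []
    g2t = gene2terms[gene2terms["gene_id"].isin(background_u)]
    N, n = len(background_u), len(gene_set_u)
    tested: list[tuple[str, str, int, int]] = []
    for (term_id, term_name), grp in g2t.groupby(["term_id", "term_name"], sort=True):
        members = set(grp["gene_id"])
        K = len(members)
        if K < min_term_genes:
            continue
        k = len(members & gene_set_u)
        tested.append((str(term_id), str(term_name), k, K))
    if not tested:
        return []
    pvals = [hypergeom_upper_tail(k, N, K, n) for _, _, k, K in tested]
    padj = bonferroni(pvals, m=len(tested))
    results = [
        EnrichmentResult(
            category=term_id, name=term_name, k=k, n=n, K=K, N=N,
            p=p, p_corrected=float(pc),
            ratio=(k / n) / (K / N),
        )
        for (term_id, term_name, k, K), p, pc in zip(tested, pvals, padj)
    ]
    results.sort(key=lambda r: (r.p_corrected, r.p, r.category))
    return results


def pairs_to_frame(pairs: Sequence[AssociationPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "dmr_id": p.dmr_id,
                "gene_id": p.gene_id,
                "proximity": p.proximity,
                "delta_m": p.delta_m,
                "delta_e": p.delta_e,
                "sign_class": p.sign_class,
            }
            for p in pairs
        ],
        columns=["dmr_id", "gene_id", "proximity", "delta_m", "delta_e", "sign_class"],
    )


def pairs_from_frame(df: pd.DataFrame) -> list[AssociationPair]:
    return [
        AssociationPair(
            dmr_id=str(r.dmr_id), gene_id=str(r.gene_id), proximity=str(r.proximity),
            delta_m=float(r.delta_m), delta_e=float(r.delta_e),
            sign_class=None if pd.isna(r.sign_class) else str(r.sign_class),
        )
        for r in df.itertuples(index=False)
    ]
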