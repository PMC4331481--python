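"""Genomic context of T-DMR classes.

Four characterizations: (1) mutually exclusive feature categories assigned
by DMR midpoint with gene-body precedence; (2) overlap enrichment against
DNase I hypersensitivity sites (DHSs) with a length-preserving placement
null; (3) empirical CDFs of per-CpG conservation scores per class; and
(4) the CpG observed/expected ratio of a sequence.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import logger
from .model import DHSPeak, GeneModel, GenomicInterval, TDMR
from .stats import binom_upper_tail, two_set_proportion_test
from scipy import stats as sps

__all__ = [
    "CATEGORIES",
    "categorize_location",
    "categorize_locations",
    "location_distribution_compare",
    "classify_dhs",
    "dhs_overlap_enrichment",
    "conservation_ecdf",
    "cpg_ratio",
]

#: Mutually exclusive feature labels, in precedence order: gene body beats
#: flanks, flanks beat intergenic.
CATEGORIES = ("5utr_or_first_exon", "exon", "intron", "upstream", "downstream", "intergenic")


def _gene_trees(genes: Sequence[GeneModel], flank: int) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        iv = g.interval
        trees[iv.chrom].addi(max(0, iv.start - flank), iv.end + flank, g)
    return dict(trees)


def _category_for_gene(
    mid: int, gene: GeneModel, upstream_bp: int, downstream_bp: int
) -> str | None:
    iv = gene.interval
    if iv.start <= mid < iv.end:
        first = gene.first_exon
        for ex in gene.exons:
            if ex.start <= mid < ex.end:
                return "5utr_or_first_exon" if ex == first else "exon"
        return "intron"
    if gene.strand == "+":
        upstream = iv.start - upstream_bp <= mid < iv.start
        downstream = iv.end <= mid < iv.end + downstream_bp
    else:
        upstream = iv.end <= mid < iv.end + upstream_bp
        downstream = iv.start - downstream_bp <= mid < iv.start
    if upstream:
        return "upstream"
    if downstream:
        return "downstream"
    return None


def categorize_locations(
    dmrs: Sequence[TDMR],
    genes: Sequence[GeneModel],
    upstream_bp: int = 4000,
    downstream_bp: int = 4000,
) -> dict[str, str]:
    """Feature category per DMR midpoint, dmr_id -> label.

    Precedence when several genes are in reach: first-exon/5'UTR > exon >
    intron > upstream > downstream > intergenic — a gene body always beats a
    neighbouring gene's flank.
    """
    trees = _gene_trees(genes, max(upstream_bp, downstream_bp))
    rank = {c: i for i, c in enumerate(CATEGORIES)}
    out: dict[str, str] = {}
    for dmr in dmrs:
        mid = dmr.interval.midpoint
        tree = trees.get(dmr.interval.chrom)
        best = "intergenic"
        if tree is not None:
            for hit in tree.at(mid):
                cat = _category_for_gene(mid, hit.data, upstream_bp, downstream_bp)
                if cat is not None and rank[cat] < rank[best]:
                    best = cat
        out[dmr.dmr_id] = best
    return out


def categorize_location(
    dmr: TDMR,
    genes: Sequence[GeneModel],
    upstream_bp: int = 4000,
    downstream_bp: int = 4000,
) -> str:
    return categorize_locations([dmr], genes, upstream_bp, downstream_bp)[dmr.dmr_id]


def location_distribution_compare(
    pos_categories: Sequence[str], neg_categories: Sequence[str]
) -> pd.DataFrame:
    """Per-category proportions of the two DMR classes plus a one-sided
    binomial test of the positive-class proportion against the negative-class
    proportion as reference."""
    if not pos_categories or not neg_categories:
        raise ValueError("both category lists must be non-empty")
    n1, n2 = len(pos_categories), len(neg_categories)
    rows = []
    for cat in CATEGORIES:
        k1 = sum(c == cat for c in pos_categories)
        k2 = sum(c == cat for c in neg_categories)
        rows.append(
            {
                "category": cat,
                "positive_count": k1,
                "positive_fraction": k1 / n1,
                "negative_count": k2,
                "negative_fraction": k2 / n2,
                "p": two_set_proportion_test(k1, n1, k2, n2),
            }
        )
    return pd.DataFrame(rows)


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _coverage_regions(
    replicate_sets: Sequence[Sequence[GenomicInterval]], k: int
) -> dict[str, list[tuple[int, int]]]:
    """Regions covered by >= k of the replicate interval sets, per chromosome."""
    events: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for rep in replicate_sets:
        merged_by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for iv in rep:
            merged_by_chrom[iv.chrom].append((iv.start, iv.end))
        for chrom, ivs in merged_by_chrom.items():
            for s, e in _merge(ivs):  # each replicate counts once per base
                events[chrom].append((s, 1))
                events[chrom].append((e, -1))
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, evs in events.items():
        evs.sort()
        regions: list[tuple[int, int]] = []
        depth = 0
        open_start: int | None = None
        for pos, delta in evs:
            new_depth = depth + delta
            if depth < k <= new_depth:
                open_start = pos
            elif new_depth < k <= depth and open_start is not None:
                regions.append((open_start, pos))
                open_start = None
            depth = new_depth
        out[chrom] = _merge(regions)
    return out


def classify_dhs(
    peaks_t1: Sequence[Sequence[GenomicInterval]] | Sequence[GenomicInterval],
    peaks_t2: Sequence[Sequence[GenomicInterval]] | Sequence[GenomicInterval],
    k_t1: int = 1,
    k_t2: int = 1,
) -> list[DHSPeak]:
    """Consensus DHS calling and shared/tissue-specific classification.

    Each tissue's argument is a list of replicate peak sets (a flat list of
    intervals is treated as a single replicate).  A region is a DHS when
    covered by >= k replicate sets for that tissue.  A DHS overlapping
    (>= 1 bp) the other tissue's DHS set is *shared* (shared regions from
    the two tissues are merged); the rest are tissue-specific.
    """
    reps1 = _as_replicates(peaks_t1)
    reps2 = _as_replicates(peaks_t2)
    if k_t1 > len(reps1) or k_t2 > len(reps2):
        raise ValueError("replicate threshold k exceeds number of replicates")
    dhs1 = _coverage_regions(reps1, k_t1)
    dhs2 = _coverage_regions(reps2, k_t2)
    out: list[DHSPeak] = []
    for chrom in sorted(set(dhs1) | set(dhs2)):
        r1, r2 = dhs1.get(chrom, []), dhs2.get(chrom, [])
        shared_parts: list[tuple[int, int]] = []
        spec1 = []
        for s, e in r1:
            if _any_overlap(s, e, r2):
                shared_parts.append((s, e))
            else:
                spec1.append((s, e))
        spec2 = []
        for s, e in r2:
            if _any_overlap(s, e, r1):
                shared_parts.append((s, e))
            else:
                spec2.append((s, e))
        for s, e in _merge(shared_parts):
            out.append(DHSPeak(GenomicInterval(chrom, s, e), "shared"))
        for s, e in spec1:
            out.append(DHSPeak(GenomicInterval(chrom, s, e), "tissue1_specific"))
        for s, e in spec2:
            out.append(DHSPeak(GenomicInterval(chrom, s, e), "tissue2_specific"))
    return out


def _as_replicates(arg) -> list[list[GenomicInterval]]:
    arg = list(arg)
    if not arg:
        return [[]]
    if isinstance(arg[0], GenomicInterval):
        return [arg]
    return [list(rep) for rep in arg]


def _any_overlap(s: int, e: int, sorted_regions: list[tuple[int, int]]) -> bool:
    starts = [r[0] for r in sorted_regions]
    import bisect

    i = bisect.bisect_left(starts, e)
    return i > 0 and sorted_regions[i - 1][1] > s


@dataclass(frozen=True)
class OverlapEnrichment:
    """Observed vs expected fraction of DMRs overlapping a peak set."""

    n_dmrs: int
    observed_count: int
    observed_fraction: float
    expected_fraction: float
    expected_sd: float
    p: float
    direction: str  # enriched | depleted
    n_shuffles: int


def dhs_overlap_enrichment(
    dmrs: Sequence[TDMR],
    dhs: Sequence[DHSPeak] | Sequence[GenomicInterval],
    probe_space: Sequence[GenomicInterval],
    n_shuffles: int = 1000,
    seed: int = 0,
) -> OverlapEnrichment:
    """Overlap of DMRs with a DHS set versus random placement.

    The expected fraction is the mean overlap of length-preserving uniform
    placements of each DMR within the probe space (the array-assayable
    intervals).  The tail is binomial at the expected per-DMR rate: upper
    when observed >= expected (enrichment), lower otherwise (depletion).
    """
    if not dmrs:
        raise ValueError("no DMRs supplied")
    peak_ivs = [p.interval if isinstance(p, DHSPeak) else p for p in dhs]
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for iv in peak_ivs:
        by_chrom[iv.chrom].append((iv.start, iv.end))
    merged = {c: _merge(ivs) for c, ivs in by_chrom.items()}
    starts = {c: np.array([s for s, _ in m]) for c, m in merged.items()}
    ends = {c: np.array([e for _, e in m]) for c, m in merged.items()}

    def overlaps(chrom: str, s: np.ndarray, e: np.ndarray) -> np.ndarray:
        if chrom not in starts or starts[chrom].size == 0:
            return np.zeros(len(s), dtype=bool)
        idx = np.searchsorted(starts[chrom], e, side="left")
        hit = idx > 0
        hit[hit] = ends[chrom][idx[hit] - 1] > s[hit]
        return hit

    lengths = np.array([d.interval.length for d in dmrs])
    space = sorted(probe_space, key=lambda iv: (iv.chrom, iv.start))
    max_len = int(lengths.max())
    if all(iv.length < max_len for iv in space):
        raise ValueError("probe space shorter than the longest DMR")

    obs = 0
    for d in dmrs:
        iv = d.interval
        obs += bool(
            overlaps(iv.chrom, np.array([iv.start]), np.array([iv.end]))[0]
        )
    observed_fraction = obs / len(dmrs)

    # length-preserving random placement within the probe space
    rng = np.random.default_rng(seed)
    space_chroms = [iv.chrom for iv in space]
    space_starts = np.array([iv.start for iv in space])
    space_lens = np.array([iv.length for iv in space])
    fracs = np.empty(n_shuffles, dtype=float)
    slots = space_lens[None, :] - lengths[:, None] + 1  # valid starts per interval
    slots = np.maximum(slots, 0)
    totals = slots.sum(axis=1)
    cum = np.cumsum(slots, axis=1)
    for t in range(n_shuffles):
        u = rng.integers(0, totals)  # uniform over all valid start positions
        which = (u[:, None] >= cum).sum(axis=1)
        offset = u - np.where(which > 0, cum[np.arange(len(u)), which - 1], 0)
        s = space_starts[which] + offset
        e = s + lengths
        hits = np.zeros(len(dmrs), dtype=bool)
        for ci, chrom in enumerate(space_chroms):
            mask = which == ci
            if mask.any():
                hits[mask] = overlaps(chrom, s[mask], e[mask])
        fracs[t] = hits.mean()
    expected_fraction = float(fracs.mean())

    if observed_fraction >= expected_fraction:
        p = binom_upper_tail(obs, len(dmrs), expected_fraction)
        direction = "enriched"
    else:
        p = float(sps.binom.cdf(obs, len(dmrs), expected_fraction))
        direction = "depleted"
    return OverlapEnrichment(
        n_dmrs=len(dmrs),
        observed_count=obs,
        observed_fraction=observed_fraction,
        expected_fraction=expected_fraction,
        expected_sd=float(fracs.std(ddof=1)),
        p=p,
        direction=direction,
        n_shuffles=n_shuffles,
    )


def conservation_ecdf(
    scores_by_class: Mapping[str, Sequence[float]], n_grid: int = 101
) -> pd.DataFrame:
    """Empirical CDF of conservation scores per class on a fixed [0, 1] grid.

    The value at grid point x is the fraction of scores <= x, so classes
    whose curve lies higher are *less* conserved.  Empty classes are omitted
    with a warning.
    """
    grid = np.linspace(0.0, 1.0, n_grid)
    data = {"score": grid}
    for cls, scores in scores_by_class.items():
        arr = np.sort(np.asarray(scores, dtype=float))
        if arr.size == 0:
            logger.warning("conservation_ecdf: class %r has no scores; omitted", cls)
            continue
        if arr.min() < 0 or arr.max() > 1:
            raise ValueError(f"class {cls!r}: scores must lie in [0, 1]")
        data[cls] = np.searchsorted(arr, grid, side="right") / arr.size
    return pd.DataFrame(data)


class CpGRatio(NamedTuple):
    """Observed/expected CpG ratio; ``defined`` is False when the sequence
    has no C or no G."""

    value: float
    defined: bool


def cpg_ratio(sequence: str) -> CpGRatio:
    """CpG observed/expected ratio: (n_CpG * L) / (n_C * n_G).

    ``n_CpG`` counts "CG" dinucleotides in an overlapping scan on the given
    strand; ``L`` is the number of valid (ACGT) positions.  Positions with
    other characters are skipped in all counts, with a warning.
    """
    if len(sequence) < 2:
        raise ValueError("sequence must have length >= 2")
    seq = sequence.upper()
    valid = [c in "ACGT" for c in seq]
    if not all(valid):
        logger.warning("cpg_ratio: %d non-ACGT positions skipped", valid.count(False))
    L = sum(valid)
    n_c = sum(1 for c, v in zip(seq, valid) if v and c == "C")
    n_g = sum(1 for c, v in zip(seq, valid) if v and c == "G")
    n_cg = sum(
        1
        for i in range(len(seq) - 1)
        if valid[i] and valid[i + 1] and seq[i] == "C" and seq[i + 1] == "G"
    )
    denom = n_c * n_g
    if denom == 0:
        return CpGRatio(0.0, False)
    return CpGRatio(n_cg * L / denom, True)
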