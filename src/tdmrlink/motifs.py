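"""Exhaustive k-mer motif discovery in T-DMR sequence classes.

All 4^k k-mers (k = 6 by default) are counted on the forward strand with
overlapping matches in a target sequence set and a length-matched random
background sampled from gene windows.  Each k-mer's target count is tested
against the pooled background rate with an exact binomial upper tail;
q-values come from Benjamini–Hochberg over the whole k-mer universe.  A
k-mer significant in the negative-class analysis only is a *negative*
motif, in the positive-class only a *positive* motif, in both a *dual*
motif.  CpG content of a motif set is tested hypergeometrically against the
universe (1,185 of the 4,096 6-mers contain a CpG).  No reverse-complement
canonicalization and no position-weight matrices: exact string matching
only.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .io import logger
from .model import GeneModel, MotifClassification, MotifResult
from .stats import ShuffleSummary, bh_fdr, hypergeom_upper_tail, shuffle_zscore

__all__ = [
    "enumerate_kmers",
    "count_kmers",
    "sample_background",
    "kmer_enrichment",
    "classify_motifs",
    "cpg_motif_fraction",
    "cross_analysis_consistency",
]

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def enumerate_kmers(k: int) -> list[str]:
    """All 4^k DNA strings of length k in lexicographic order."""
    if not 1 <= k <= 12:
        raise ValueError("k must be in 1..12")
    return ["".join(t) for t in itertools.product("ACGT", repeat=k)]


def count_kmers(seqs: Sequence[str], k: int) -> tuple[np.ndarray, int]:
    """Overlapping forward-strand k-mer counts pooled over sequences.

    Returns (counts over the 4^k universe in lexicographic order, number of
    valid positions).  A position is valid when all k bases are ACGT;
    invalid positions are excluded from both counts and positions.
    """
    if not seqs:
        return np.zeros(4**k, dtype=np.int64), 0
    # join with one N: a window crossing a boundary always contains it
    joined = "N".join(s.upper() for s in seqs)
    codes = _CODE[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)]
    if codes.size < k:
        return np.zeros(4**k, dtype=np.int64), 0
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    idx = windows[valid] @ powers
    counts = np.bincount(idx, minlength=4**k)
    return counts, int(valid.sum())


def sample_background(
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    target_lengths: Sequence[int],
    multiplier: int = 10,
    upstream_bp: int = 4000,
    seed: int = 0,
    max_retries: int = 50,
) -> list[str]:
    """Length-matched random background segments from gene windows.

    Each target length is drawn exactly ``multiplier`` times.  For every
    draw a gene window (upstream_bp upstream of the TSS through the
    transcription end, clipped to the chromosome) is chosen uniformly among
    those long enough, and the segment start is uniform within it.  Draws
    with no feasible window are retried, then skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    windows = []
    for g in genes:
        w = g.regulatory_window(upstream_bp)
        chrom_len = len(genome[w.chrom])
        lo, hi = max(0, w.start), min(chrom_len, w.end)
        if hi > lo:
            windows.append((w.chrom, lo, hi))
    if not windows:
        raise ValueError("no usable gene windows")
    win_lens = np.array([hi - lo for _, lo, hi in windows])
    out: list[str] = []
    n_skipped = 0
    for L in target_lengths:
        for _ in range(multiplier):
            seg = None
            for _try in range(max_retries):
                wi = int(rng.integers(0, len(windows)))
                if win_lens[wi] < L:
                    continue
                chrom, lo, hi = windows[wi]
                s = int(rng.integers(lo, hi - L + 1))
                seg = genome[chrom][s : s + L]
                break
            if seg is None:
                n_skipped += 1
            else:
                out.append(seg)
    if n_skipped:
        logger.warning("sample_background: %d draws had no feasible window; skipped",
                       n_skipped)
    return out


def kmer_enrichment(
    target_seqs: Sequence[str],
    bg_seqs: Sequence[str],
    k: int = 6,
    fdr_threshold: float = 0.01,
) -> list[MotifResult]:
    """Per-k-mer binomial enrichment of a target set against a background.

    p = P(X >= count_target) for X ~ Binomial(positions_target, p0) with
    p0 the background's pooled rate; q = BH over all 4^k k-mers.  The
    log2 enrichment score carries a 0.5 pseudocount on both counts (the
    test does not).  A k-mer with zero background occurrences and a nonzero
    target count gets p = 0 and is flagged as a boundary case.
    """
    if not target_seqs or not bg_seqs:
        raise ValueError("both sequence sets must be non-empty")
    kmers = enumerate_kmers(k)
    ct, pos_t = count_kmers(target_seqs, k)
    cb, pos_b = count_kmers(bg_seqs, k)
    if pos_t == 0 or pos_b == 0:
        raise ValueError("no valid k-mer positions in one of the sets")
    p0 = cb / pos_b
    # exact inclusive upper tail, vectorized over the universe
    p = sps.binom.sf(ct - 1, pos_t, p0)
    p = np.where(ct == 0, 1.0, p)
    boundary = (cb == 0) & (ct > 0)
    p = np.where(boundary, 0.0, p)
    q = bh_fdr(p)
    score = np.log2(((ct + 0.5) / pos_t) / ((cb + 0.5) / pos_b))
    return [
        MotifResult(
            kmer=kmers[i],
            count_target=int(ct[i]),
            positions_target=pos_t,
            count_bg=int(cb[i]),
            positions_bg=pos_b,
            p=float(p[i]),
            q=float(q[i]),
            enrichment_score=float(score[i]),
            significant=bool(q[i] < fdr_threshold),
            boundary=bool(boundary[i]),
        )
        for i in range(len(kmers))
    ]


def classify_motifs(
    results_negative: Sequence[MotifResult],
    results_positive: Sequence[MotifResult],
) -> list[MotifClassification]:
    """Role per k-mer: negative / positive when significant in exactly one
    class analysis, dual when significant in both, none otherwise."""
    if [r.kmer for r in results_negative] != [r.kmer for r in results_positive]:
        raise ValueError("result lists cover different k-mer universes")
    out = []
    for rn, rp in zip(results_negative, results_positive):
        if rn.significant and rp.significant:
            role = "dual"
        elif rn.significant:
            role = "negative"
        elif rp.significant:
            role = "positive"
        else:
            role = "none"
        out.append(MotifClassification(kmer=rn.kmer, role=role))
    return out


def n_cpg_kmers(k: int) -> int:
    """Number of k-mers containing the dinucleotide CG, by enumeration."""
    return sum(1 for m in enumerate_kmers(k) if "CG" in m)


@dataclass(frozen=True)
class CpGFraction:
    fraction: float
    universe_fraction: float
    p: float
    direction: str  # enriched | depleted
    n_motifs: int


def cpg_motif_fraction(motifs: Sequence[str], universe_k: int = 6) -> CpGFraction:
    """Share of motifs containing a CpG, tested against the k-mer universe.

    The universe contains 1,185 CpG-bearing 6-mers out of 4,096 (28.9%);
    the test is hypergeometric, upper tail when the set is at or above the
    universe fraction, lower tail otherwise.
    """
    if not motifs:
        raise ValueError("empty motif list")
    if any(len(m) != universe_k for m in motifs):
        raise ValueError(f"all motifs must have length {universe_k}")
    N = 4**universe_k
    K = n_cpg_kmers(universe_k)
    n = len(motifs)
    kk = sum(1 for m in motifs if "CG" in m.upper())
    frac = kk / n
    if frac >= K / N:
        p = hypergeom_upper_tail(kk, N, K, n)
        direction = "enriched"
    else:
        p = float(sps.hypergeom.cdf(kk, N, K, n))
        direction = "depleted"
    return CpGFraction(fraction=frac, universe_fraction=K / N, p=p,
                       direction=direction, n_motifs=n)


@dataclass(frozen=True)
class ConsistencySummary:
    """Agreement between two analyses' significant motif sets."""

    overlap: ShuffleSummary
    role_agreement: ShuffleSummary


def cross_analysis_consistency(
    set_a: Sequence[str],
    set_b: Sequence[str],
    roles_a: Mapping[str, str],
    roles_b: Mapping[str, str],
    universe: int = 4096,
    n_shuffles: int = 10000,
    seed: int = 0,
) -> ConsistencySummary:
    """Observed vs null overlap of two significant-motif sets, and role
    agreement on the intersection.

    Null: each analysis draws its set size uniformly without replacement
    from the universe, carrying its own role labels (so role proportions
    are preserved); overlap and same-role counts are recomputed per draw.
    """
    a = sorted(set(set_a))
    b = sorted(set(set_b))
    if len(a) > universe or len(b) > universe:
        raise ValueError("set larger than universe")
    obs_overlap = len(set(a) & set(b))
    obs_agree = sum(1 for m in set(a) & set(b) if roles_a[m] == roles_b[m])

    role_codes = {"negative": 0, "positive": 1, "dual": 2}
    codes_a = np.array([role_codes[roles_a[m]] for m in a], dtype=np.int8)
    codes_b = np.array([role_codes[roles_b[m]] for m in b], dtype=np.int8)
    rng = np.random.default_rng(seed)
    null_overlap = np.empty(n_shuffles, dtype=np.int64)
    null_agree = np.empty(n_shuffles, dtype=np.int64)
    ra = np.empty(universe, dtype=np.int8)
    rb = np.empty(universe, dtype=np.int8)
    for t in range(n_shuffles):
        ra.fill(-1)
        rb.fill(-1)
        ra[rng.choice(universe, size=len(a), replace=False)] = codes_a
        rb[rng.choice(universe, size=len(b), replace=False)] = codes_b
        inter = (ra >= 0) & (rb >= 0)
        null_overlap[t] = int(inter.sum())
        null_agree[t] = int((inter & (ra == rb)).sum())
    return ConsistencySummary(
        overlap=shuffle_zscore(obs_overlap, null_overlap),
        role_agreement=shuffle_zscore(obs_agree, null_agree),
    )
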