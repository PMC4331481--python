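"""Synthetic datasets with planted structure for every pipeline stage.

The generator lays out a random genome with non-overlapping genes, places
differentially methylated regions (DMRs) inside strand-aware gene windows,
draws per-tissue methylation and replicate expression so that a configured
fraction of (DMR, gene) pairs is sign-concordant, plants multi-DMR genes with
a configurable coherence bias, builds DNase-hypersensitivity tracks with a
planted DMR-overlap fraction, spikes 6-mers into class-labelled DMR
sequences, and emits per-CpG conservation scores with class-dependent shifts.

Truth tables record every planted label so downstream recovery is
measurable.  All outputs are deterministic given ``SimConfig.seed``: each
operation draws from its own fixed substream of the seed, so skipping one
stage never perturbs another.

Default sizes mirror a two-tissue methylation-array study: ~2,500 DMRs of
200–2,000 bp, 34% sign-concordant pairs, expression in triplicate vs
duplicate, an 18% DMR/DHS overlap against a 13% random expectation, and 35%
of DHS peaks shared between tissues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    DELTA_E_THRESHOLD,
    ExpressionRecord,
    GeneModel,
    GenomicInterval,
    TDMR,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class SimulationError(ValueError):
    """Requested configuration is infeasible (placement, coverage, ...)."""


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with study-scale defaults."""

    # genome layout
    n_genes: int = 1800
    gene_len_range: tuple[int, int] = (3000, 12000)
    # gaps large enough that 4 kb upstream windows of neighbours never meet
    intergenic_len_range: tuple[int, int] = (8200, 12000)
    gc_content: float = 0.42
    chrom: str = "chrS1"
    exon_count_range: tuple[int, int] = (2, 5)

    # DMRs and planted sign structure
    n_dmrs: int = 2498
    dmr_len_range: tuple[int, int] = (200, 2000)
    frac_positive: float = 0.34
    frac_multi_dmr_genes: float = 0.25
    multi_dmr_count_range: tuple[int, int] = (2, 4)
    coherence_bias: float = 0.8
    frac_subthreshold: float = 0.15
    upstream_bp: int = 4000

    # effect sizes and noise
    delta_e_sd: float = 1.0
    delta_m_sd: float = 0.2
    delta_m_floor: float = 0.1
    rep_noise_sd: float = 0.2
    n_reps_t1: int = 3
    n_reps_t2: int = 2

    # DNase hypersensitivity
    dhs_cover_frac: float = 0.13  # target null placement-overlap probability
    dhs_dmr_overlap_frac: float = 0.18
    dhs_shared_frac: float = 0.35
    dhs_peak_len_range: tuple[int, int] = (150, 600)

    # motif planting: (6-mer, per-sequence insertion rate)
    planted_motifs_pos: tuple[tuple[str, float], ...] = ()
    planted_motifs_neg: tuple[tuple[str, float], ...] = ()

    # conservation
    cons_base_mean: float = 0.25
    cons_base_sd: float = 0.15
    cons_shift_positive: float = 0.2
    cons_shift_negative: float = 0.1
    cons_shift_exon: float = 0.35

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_positive", "frac_multi_dmr_genes", "coherence_bias",
                     "frac_subthreshold", "dhs_cover_frac", "dhs_dmr_overlap_frac",
                     "dhs_shared_frac", "gc_content"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("gene_len_range", "intergenic_len_range", "dmr_len_range",
                     "dhs_peak_len_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (lo, hi) range")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic substream per pipeline stage."""
        return np.random.default_rng([self.seed, stream])


# substream ids, one per operation
_S_LAYOUT, _S_SEQ, _S_METH, _S_DHS, _S_MOTIF, _S_CONS = range(1, 7)


def generate_genes(config: SimConfig) -> tuple[list[GeneModel], int]:
    """Lay out non-overlapping genes on one chromosome, alternating strand.

    Returns the gene models and the chromosome length.  Uses its own random
    substream, so the layout is identical whether or not sequence is
    generated.
    """
    rng = config.rng(_S_LAYOUT)
    glo, ghi = config.gene_len_range
    ilo, ihi = config.intergenic_len_range
    lengths = rng.integers(glo, ghi + 1, size=config.n_genes)
    gaps = rng.integers(ilo, ihi + 1, size=config.n_genes + 1)
    genes: list[GeneModel] = []
    pos = int(gaps[0])
    elo, ehi = config.exon_count_range
    for i, (length, gap) in enumerate(zip(lengths, gaps[1:])):
        length = int(length)
        strand = "+" if i % 2 == 0 else "-"
        iv = GenomicInterval(config.chrom, pos, pos + length, strand)
        n_exons = int(rng.integers(elo, ehi + 1))
        exons = _random_exons(rng, iv, n_exons)
        genes.append(GeneModel(gene_id=f"g{i:05d}", interval=iv, exons=exons))
        pos += length + int(gap)
    return genes, pos


def _random_exons(
    rng: np.random.Generator, iv: GenomicInterval, n_exons: int
) -> tuple[GenomicInterval, ...]:
    """Split a gene span into alternating exon/intron segments (exons at both
    ends, as in a real transcript)."""
    n_cuts = 2 * (n_exons - 1)
    if n_cuts == 0:
        return (iv,)
    if iv.length <= n_cuts + 1:
        return (iv,)
    cuts = np.sort(rng.choice(np.arange(1, iv.length), size=n_cuts, replace=False))
    bounds = np.concatenate([[0], cuts, [iv.length]])
    return tuple(
        GenomicInterval(iv.chrom, iv.start + int(bounds[j]), iv.start + int(bounds[j + 1]),
                        iv.strand)
        for j in range(0, len(bounds) - 1, 2)
    )


def generate_genome_and_genes(config: SimConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Genes plus an i.i.d. background sequence with the configured GC."""
    genes, chrom_len = generate_genes(config)
    rng = config.rng(_S_SEQ)
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(_BASES, size=chrom_len, p=probs).tobytes().decode("ascii")
    return {config.chrom: seq}, genes


def generate_methylation_expression(
    config: SimConfig, genes: Sequence[GeneModel]
) -> tuple[list[TDMR], list[ExpressionRecord], pd.DataFrame]:
    """Plant DMRs inside gene windows with the configured sign structure.

    Every gene gets an expression record.  A fraction ``frac_subthreshold``
    of host genes gets a true |ΔE| below the fold-change threshold (their
    pairs carry planted class ``subthreshold``); all other host genes'
    planted pairs are informative, with true |ΔE| strictly above it.  The
    truth table has one row per (DMR, gene) pair with the planted relation.
    """
    rng = config.rng(_S_METH)
    order = rng.permutation(len(genes))

    # decide hosting: walk genes in random order, multi-DMR hosts get 2..hi DMRs
    mlo, mhi = config.multi_dmr_count_range
    counts: list[tuple[int, int]] = []  # (gene index, n_dmrs)
    total = 0
    for gi in order:
        if total >= config.n_dmrs:
            break
        k = 1
        if rng.random() < config.frac_multi_dmr_genes:
            k = int(rng.integers(mlo, mhi + 1))
        k = min(k, config.n_dmrs - total)
        counts.append((int(gi), k))
        total += k
    if total < config.n_dmrs:
        raise SimulationError(
            f"cannot place {config.n_dmrs} DMRs on {len(genes)} genes; add genes"
        )
    host = {gi: k for gi, k in counts}

    thresh = DELTA_E_THRESHOLD
    dmrs: list[TDMR] = []
    exprs: list[ExpressionRecord] = []
    truth_rows: list[dict] = []
    dmr_no = 0
    for gi, gene in enumerate(genes):
        k = host.get(gi, 0)
        informative = True
        if k > 0 and rng.random() < config.frac_subthreshold:
            informative = False
        # true expression effect
        sign_e = 1.0 if rng.random() < 0.5 else -1.0
        if informative:
            mag_e = thresh + 0.05 + abs(rng.normal(0.0, config.delta_e_sd))
        else:
            mag_e = rng.uniform(0.0, 0.95 * thresh)
        true_de = sign_e * mag_e
        base = rng.uniform(3.0, 10.0)
        reps1 = base + true_de + rng.normal(0.0, config.rep_noise_sd, config.n_reps_t1)
        reps2 = base + rng.normal(0.0, config.rep_noise_sd, config.n_reps_t2)
        exprs.append(
            ExpressionRecord(gene.gene_id, tuple(map(float, reps1)), tuple(map(float, reps2)))
        )
        if k == 0:
            continue

        window = gene.regulatory_window(config.upstream_bp)
        lengths = _feasible_lengths(rng, config, k, window.length, gene.gene_id)
        starts = _pack_intervals(rng, window.start, window.length, lengths)

        coherent = len(lengths) >= 2 and rng.random() < config.coherence_bias
        shared_rel = rng.random() < config.frac_positive
        for L, s in zip(lengths, starts):
            rel_positive = shared_rel if coherent else (rng.random() < config.frac_positive)
            sign_m = sign_e if rel_positive else -sign_e
            mag_m = min(config.delta_m_floor + abs(rng.normal(0.0, config.delta_m_sd)), 0.8)
            dm = sign_m * mag_m
            center = rng.uniform(mag_m / 2 + 0.01, 1 - mag_m / 2 - 0.01)
            dmr_id = f"dmr{dmr_no:05d}"
            dmr_no += 1
            dmrs.append(
                TDMR(dmr_id, GenomicInterval(window.chrom, s, s + L),
                     m_tissue1=center + dm / 2, m_tissue2=center - dm / 2)
            )
            truth_rows.append(
                {
                    "dmr_id": dmr_id,
                    "gene_id": gene.gene_id,
                    "planted_relation": "positive" if rel_positive else "negative",
                    "planted_class": ("positive" if rel_positive else "negative")
                    if informative else "subthreshold",
                    "true_delta_e": true_de,
                    "delta_m": dm,
                    "coherent_gene": coherent,
                    "n_dmrs_gene": len(lengths),
                }
            )
    return dmrs, exprs, pd.DataFrame(truth_rows)


def _feasible_lengths(
    rng: np.random.Generator, config: SimConfig, k: int, window_len: int, gene_id: str
) -> list[int]:
    lo, hi = config.dmr_len_range
    lengths = [int(x) for x in rng.integers(lo, hi + 1, size=k)]
    while lengths and sum(lengths) > window_len:
        lengths.pop()
    if not lengths:
        raise SimulationError(
            f"gene {gene_id}: window ({window_len} bp) cannot hold any DMR of "
            f">= {lo} bp"
        )
    return lengths


def _pack_intervals(
    rng: np.random.Generator, w_start: int, w_len: int, lengths: Sequence[int]
) -> list[int]:
    """Place non-overlapping intervals of the given lengths uniformly in a
    window (stars-and-bars over the free space)."""
    free = w_len - sum(lengths)
    cuts = np.sort(rng.integers(0, free + 1, size=len(lengths)))
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    return [w_start + int(c) + int(o) for c, o in zip(cuts, offsets)]


def generate_dhs_tracks(
    config: SimConfig, dmrs: Sequence[TDMR], genome_span: int
) -> tuple[list[GenomicInterval], list[GenomicInterval], dict]:
    """DNase-hypersensitivity peak sets for the two tissues.

    A planted fraction ``dhs_dmr_overlap_frac`` of DMRs receives a peak
    strictly inside it; background peaks are placed away from every DMR
    until the analytic probability that a random length-preserving DMR
    placement overlaps a peak reaches ``dhs_cover_frac``.  Each peak is
    shared between tissues with probability ``dhs_shared_frac``, else
    assigned to one tissue.

    Returns (peaks_tissue1, peaks_tissue2, truth) where truth carries the
    planted overlap fraction, the analytic null expectation and per-peak
    classes.
    """
    rng = config.rng(_S_DHS)
    n_overlap = int(round(config.dhs_dmr_overlap_frac * len(dmrs)))
    plo, phi = config.dhs_peak_len_range
    chrom = dmrs[0].interval.chrom if dmrs else config.chrom

    peaks: list[GenomicInterval] = []
    overlapped_ids: list[str] = []
    if n_overlap > 0:
        chosen = rng.choice(len(dmrs), size=n_overlap, replace=False)
        for idx in chosen:
            d = dmrs[int(idx)].interval
            peak_len = min(int(rng.integers(plo, phi + 1)), d.length)
            start = d.start + int(rng.integers(0, d.length - peak_len + 1))
            peaks.append(GenomicInterval(chrom, start, start + peak_len))
            overlapped_ids.append(dmrs[int(idx)].dmr_id)

    # background peaks go in gaps clear of every DMR by a full peak length
    margin = phi
    allowed = _complement_with_margin(
        [d.interval for d in dmrs], genome_span, margin, min_len=phi
    )
    if not allowed:
        raise SimulationError("no DMR-free space left for background DHS peaks")
    lengths = np.array([d.interval.length for d in dmrs], dtype=float)
    int_lengths = [int(x) for x in lengths]
    mean_len = float(lengths.mean()) if len(lengths) else 500.0
    mean_peak = (plo + phi) / 2
    gap_lens = np.array([a[1] - a[0] for a in allowed], dtype=float)
    if config.dhs_cover_frac * genome_span > gap_lens.sum():
        raise SimulationError("dhs_cover_frac infeasible for this genome span")

    def place_background(n: int) -> None:
        for _ in range(n):
            peak_len = int(rng.integers(plo, phi + 1))
            gi = int(rng.choice(len(allowed), p=gap_lens / gap_lens.sum()))
            lo, hi = allowed[gi]
            if hi - lo <= peak_len:
                continue
            start = int(rng.integers(lo, hi - peak_len))
            peaks.append(GenomicInterval(chrom, start, start + peak_len))

    # first batch from a closed-form estimate, then top up against the exact
    # placement probability until the null target is met
    current = sum(p.length + mean_len - 1 for p in peaks)
    target_starts = config.dhs_cover_frac * genome_span
    place_background(
        max(0, int(round((target_starts - current) / (mean_peak + mean_len - 1))))
    )
    for _ in range(20):
        null = analytic_placement_overlap(
            [(p.start, p.end) for p in peaks], int_lengths, genome_span
        )
        deficit = config.dhs_cover_frac - null
        if deficit <= 0.001:
            break
        place_background(
            max(1, int(round(deficit * genome_span / (mean_peak + mean_len - 1))))
        )

    classes = []
    for _ in peaks:
        r = rng.random()
        if r < config.dhs_shared_frac:
            classes.append("shared")
        else:
            classes.append("tissue1_specific" if rng.random() < 0.5 else "tissue2_specific")

    peaks_t1 = [p for p, c in zip(peaks, classes) if c in ("shared", "tissue1_specific")]
    peaks_t2 = [p for p, c in zip(peaks, classes) if c in ("shared", "tissue2_specific")]
    truth = {
        "planted_overlap_frac": n_overlap / len(dmrs) if dmrs else 0.0,
        "overlapped_dmr_ids": overlapped_ids,
        "analytic_null_frac": analytic_placement_overlap(
            [(p.start, p.end) for p in peaks], [int(x) for x in lengths], genome_span
        ),
        "peak_classes": list(zip([(p.start, p.end) for p in peaks], classes)),
    }
    return peaks_t1, peaks_t2, truth


def _complement_with_margin(
    intervals: Sequence[GenomicInterval], span: int, margin: int, min_len: int
) -> list[tuple[int, int]]:
    """Gaps of the span not within ``margin`` of any interval."""
    if not intervals:
        return [(0, span)]
    ivs = sorted((max(0, iv.start - margin), min(span, iv.end + margin)) for iv in intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    gaps = []
    prev = 0
    for s, e in merged:
        if s - prev >= min_len:
            gaps.append((prev, s))
        prev = e
    if span - prev >= min_len:
        gaps.append((prev, span))
    return gaps


def analytic_placement_overlap(
    peaks: Sequence[tuple[int, int]], dmr_lengths: Sequence[int], span: int
) -> float:
    """Exact probability that a uniformly placed interval of each given
    length overlaps >= 1 bp of the peak union, averaged over lengths."""
    if not peaks or not dmr_lengths:
        return 0.0
    peaks = sorted(peaks)
    probs = []
    for L, count in zip(*np.unique(np.asarray(dmr_lengths), return_counts=True)):
        L = int(L)
        # starts s with [s, s+L) hitting peak [a, b): s in [a-L+1, b-1]
        expanded = [(max(0, a - L + 1), min(b, span - L + 1)) for a, b in peaks]
        covered = 0
        cur_s, cur_e = expanded[0]
        for s, e in expanded[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                covered += max(0, cur_e - cur_s)
                cur_s, cur_e = s, e
        covered += max(0, cur_e - cur_s)
        probs.extend([covered / (span - L + 1)] * int(count))
    return float(np.mean(probs))


def plant_motifs(
    config: SimConfig, dmr_seqs_by_class: dict[str, list[str]]
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Overwrite k-mers into class-labelled DMR sequences at planted rates.

    Insertion (overwrite at a uniform position) keeps the length
    distribution intact, which the length-matched background sampler relies
    on.  Returns the mutated sequences and an insertion log.
    """
    rng = config.rng(_S_MOTIF)
    plan = {"positive": config.planted_motifs_pos, "negative": config.planted_motifs_neg}
    for motifs in plan.values():
        for motif, _ in motifs:
            if not motif or any(b not in "ACGT" for b in motif):
                raise ValueError(f"planted motif {motif!r} must be over ACGT")
    out: dict[str, list[str]] = {}
    log_rows: list[dict] = []
    for cls, seqs in dmr_seqs_by_class.items():
        motifs = plan.get(cls, ())
        new_seqs = []
        for si, seq in enumerate(seqs):
            s = seq
            for motif, rate in motifs:
                n_ins = int(rate) + (1 if rng.random() < rate - int(rate) else 0)
                for _ in range(n_ins):
                    if len(motif) > len(s):
                        from .io import logger

                        logger.warning("motif %s longer than sequence; skipped", motif)
                        continue
                    pos = int(rng.integers(0, len(s) - len(motif) + 1))
                    s = s[:pos] + motif + s[pos + len(motif):]
                    log_rows.append(
                        {"class": cls, "seq_index": si, "motif": motif, "pos": pos}
                    )
            new_seqs.append(s)
        out[cls] = new_seqs
    return out, pd.DataFrame(log_rows, columns=["class", "seq_index", "motif", "pos"])


def generate_conservation(
    config: SimConfig,
    dmrs: Sequence[TDMR],
    classes: dict[str, str],
    genome: dict[str, str],
    genes: Sequence[GeneModel] = (),
    n_background: int = 5000,
) -> pd.DataFrame:
    """Per-CpG conservation scores with class-dependent mean shifts.

    Emits one row per CpG site (chrom, start, end, score, class) for each
    DMR (class from ``classes``: positive/negative), for a sample of exonic
    CpGs (class ``exon``) and for a sample of genomic background CpGs
    (class ``background``).  Scores are clipped to [0, 1]; DMRs without a
    CpG contribute no rows.
    """
    rng = config.rng(_S_CONS)
    shifts = {
        "positive": config.cons_shift_positive,
        "negative": config.cons_shift_negative,
        "exon": config.cons_shift_exon,
        "background": 0.0,
    }
    out_chrom: list[np.ndarray] = []
    out_pos: list[np.ndarray] = []
    out_score: list[np.ndarray] = []
    out_cls: list[np.ndarray] = []

    def emit(chrom: str, positions: np.ndarray, cls: str) -> None:
        if positions.size == 0:
            return
        scores = np.clip(
            rng.normal(config.cons_base_mean + shifts[cls], config.cons_base_sd,
                       size=positions.size),
            0.0, 1.0,
        )
        out_chrom.append(np.full(positions.size, chrom, dtype=object))
        out_pos.append(positions.astype(np.int64))
        out_score.append(scores)
        out_cls.append(np.full(positions.size, cls, dtype=object))

    cpg_cache: dict[str, np.ndarray] = {
        chrom: _cpg_positions(seq) for chrom, seq in genome.items()
    }

    def in_range(all_pos: np.ndarray, start: int, end: int) -> np.ndarray:
        """CpG start positions with the full dinucleotide inside [start, end)."""
        i0 = np.searchsorted(all_pos, start, side="left")
        i1 = np.searchsorted(all_pos, end - 1, side="left")
        return all_pos[i0:i1]

    dmr_pos: dict[str, list[np.ndarray]] = {chrom: [] for chrom in genome}
    for d in dmrs:
        iv = d.interval
        pos = in_range(cpg_cache[iv.chrom], iv.start, iv.end)
        dmr_pos[iv.chrom].append(pos)
        cls = classes.get(d.dmr_id)
        if cls in ("positive", "negative"):
            emit(iv.chrom, pos, cls)
    dmr_pos_sorted = {
        chrom: np.unique(np.concatenate(parts)) if parts else np.empty(0, dtype=np.int64)
        for chrom, parts in dmr_pos.items()
    }

    for gene in genes:
        for ex in gene.exons:
            pos = in_range(cpg_cache[ex.chrom], ex.start, ex.end)
            pos = pos[~np.isin(pos, dmr_pos_sorted[ex.chrom], assume_unique=False)]
            if pos.size > 5:
                pos = rng.choice(pos, size=5, replace=False)
            emit(ex.chrom, pos, "exon")

    for chrom, all_pos in cpg_cache.items():
        bg = all_pos[~np.isin(all_pos, dmr_pos_sorted[chrom])]
        if bg.size > n_background:
            bg = rng.choice(bg, size=n_background, replace=False)
        emit(chrom, bg, "background")

    if not out_pos:
        return pd.DataFrame(columns=["chrom", "start", "end", "score", "class"])
    starts = np.concatenate(out_pos)
    return pd.DataFrame(
        {
            "chrom": np.concatenate(out_chrom),
            "start": starts,
            "end": starts + 2,
            "score": np.concatenate(out_score),
            "class": np.concatenate(out_cls),
        }
    )


def _cpg_positions(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    return np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G"))


def extract_sequences(genome: dict[str, str], dmrs: Sequence[TDMR]) -> list[str]:
    """DMR sequences from the genome, in input order."""
    return [genome[d.interval.chrom][d.interval.start : d.interval.end] for d in dmrs]


def random_sequences(
    lengths: Sequence[int], gc: float = 0.42, seed: int | np.random.Generator = 0
) -> list[str]:
    """I.i.d. DNA sequences of the given lengths at the given GC content."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    flat = rng.choice(_BASES, size=int(np.sum(lengths)), p=probs).tobytes().decode("ascii")
    out, pos = [], 0
    for L in lengths:
        out.append(flat[pos : pos + L])
        pos += L
    return out
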