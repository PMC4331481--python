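"""Coherence of multi-DMR genes against a ΔM-shuffling null.

A gene associated with two or more sign-classified T-DMRs is *coherent*
when every DMR has the same sign relation with its expression (all positive
or all negative) and *incoherent* otherwise.  Observed class counts are
scored against a null that keeps each gene's ΔE fixed and permutes the ΔM
values across the DMR slots of the multi-DMR genes, recomputing the sign
relation from the shuffled ΔM; the Z-score is (observed − null mean) / null
sample SD.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

import numpy as np

from .model import AssociationPair, CoherenceRecord
from .stats import ShuffleSummary, shuffle_zscore

__all__ = ["build_coherence_records", "coherence_null_test", "CLASSES"]

CLASSES = ("incoherent", "coherent_negative", "coherent_positive")


def _classified_by_gene(
    pairs: Sequence[AssociationPair],
) -> dict[str, list[AssociationPair]]:
    by_gene: dict[str, list[AssociationPair]] = defaultdict(list)
    for p in pairs:
        if p.sign_class in ("positive", "negative"):
            by_gene[p.gene_id].append(p)
    return {g: ps for g, ps in by_gene.items() if len(ps) >= 2}


def build_coherence_records(pairs: Sequence[AssociationPair]) -> list[CoherenceRecord]:
    """One record per gene with >= 2 non-excluded pairs."""
    by_gene = _classified_by_gene(pairs)
    return [
        CoherenceRecord(gene_id=g, signs=tuple(p.sign_class for p in ps))
        for g, ps in sorted(by_gene.items())
    ]


def coherence_null_test(
    pairs: Sequence[AssociationPair],
    n_shuffles: int = 10000,
    seed: int = 0,
    chunk: int = 256,
) -> dict[str, ShuffleSummary]:
    """Observed vs shuffled coherence class counts, one summary per class.

    Only the DMR slots belonging to multi-DMR genes enter the shuffle
    universe; the multiset of their ΔM values is permuted without
    replacement.  Class counts are conserved in every shuffle (they always
    sum to the number of multi-DMR genes).
    """
    by_gene = _classified_by_gene(pairs)
    if not by_gene:
        raise ValueError("no multi-DMR genes among the classified pairs")

    gene_ids = sorted(by_gene)
    dm, de_sign, starts = [], [], []
    observed = dict.fromkeys(CLASSES, 0)
    for g in gene_ids:
        ps = by_gene[g]
        starts.append(len(dm))
        for p in ps:
            dm.append(p.delta_m)
            de_sign.append(1.0 if p.delta_e > 0 else -1.0)
        rec = CoherenceRecord(gene_id=g, signs=tuple(p.sign_class for p in ps))
        observed[rec.coherence_class] += 1
    dm_arr = np.array(dm, dtype=float)
    de_sign_arr = np.array(de_sign, dtype=float)
    starts_arr = np.array(starts, dtype=np.intp)
    sizes = np.diff(np.append(starts_arr, len(dm_arr)))

    rng = np.random.default_rng(seed)
    null = {c: np.empty(n_shuffles, dtype=np.int64) for c in CLASSES}
    done = 0
    while done < n_shuffles:
        m = min(chunk, n_shuffles - done)
        perm = rng.permuted(np.tile(dm_arr, (m, 1)), axis=1)
        positive = (np.sign(perm) == de_sign_arr[None, :])
        n_pos = np.add.reduceat(positive, starts_arr, axis=1)
        coh_pos = (n_pos == sizes[None, :]).sum(axis=1)
        coh_neg = (n_pos == 0).sum(axis=1)
        null["coherent_positive"][done : done + m] = coh_pos
        null["coherent_negative"][done : done + m] = coh_neg
        null["incoherent"][done : done + m] = len(gene_ids) - coh_pos - coh_neg
        done += m

    return {c: shuffle_zscore(observed[c], null[c]) for c in CLASSES}
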