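"""Domain types shared by every stage of the pipeline.

All coordinates are 0-based, half-open (BED convention).  Conversion from
1-based inclusive systems (GTF) happens only at the I/O boundary.

The central objects are:

* :class:`GenomicInterval` — a located span with optional strand.
* :class:`GeneModel` — a gene with exons and a strand-resolved TSS.
* :class:`TDMR` — a tissue-specific differentially methylated region with
  per-tissue methylation levels; ``delta_m`` is always tissue1 − tissue2.
* :class:`ExpressionRecord` — replicate log2 expression per tissue;
  ``delta_e`` is the difference of replicate means, tissue1 − tissue2.
* :class:`AssociationPair` — one (T-DMR, gene) link with its sign class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

STRANDS = ("+", "-", ".")

#: |delta_e| must exceed this (log2 units, a 25% linear fold change) for a
#: pair to be sign-classified at all.
DELTA_E_THRESHOLD = math.log2(1.25)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>= 1 bp intersection on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene span with sorted, non-overlapping exons.

    ``tss`` and ``tx_end`` are strand-resolved base positions: for a ``+``
    gene the TSS is ``interval.start``; for a ``-`` gene it is
    ``interval.end - 1`` (the last covered base).
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand is required")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for ex in exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene span")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = ex.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tx_end(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    @property
    def first_exon(self) -> GenomicInterval | None:
        """The 5'-most exon in transcription order, if any."""
        if not self.exons:
            return None
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    def regulatory_window(self, upstream_bp: int = 4000) -> GenomicInterval:
        """Strand-aware window from ``upstream_bp`` upstream of the TSS to the
        transcription end — the region a proximal T-DMR may occupy."""
        if self.strand == "+":
            lo = max(0, self.interval.start - upstream_bp)
            hi = self.interval.end
        else:
            lo = self.interval.start
            hi = self.interval.end + upstream_bp
        return GenomicInterval(self.interval.chrom, lo, hi, self.strand)


@dataclass(frozen=True)
class TDMR:
    """A differentially methylated region with per-tissue methylation levels."""

    dmr_id: str
    interval: GenomicInterval
    m_tissue1: float
    m_tissue2: float

    @property
    def delta_m(self) -> float:
        """Methylation difference, tissue1 − tissue2."""
        return self.m_tissue1 - self.m_tissue2


@dataclass(frozen=True)
class ExpressionRecord:
    """Replicate log2 expression values for one gene in two tissues."""

    gene_id: str
    log2_reps_tissue1: tuple[float, ...]
    log2_reps_tissue2: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.log2_reps_tissue1 or not self.log2_reps_tissue2:
            raise ValueError(f"gene {self.gene_id}: empty replicate list")
        object.__setattr__(self, "log2_reps_tissue1", tuple(self.log2_reps_tissue1))
        object.__setattr__(self, "log2_reps_tissue2", tuple(self.log2_reps_tissue2))

    @property
    def delta_e(self) -> float:
        """Log2 expression difference, mean(tissue1) − mean(tissue2)."""
        t1 = sum(self.log2_reps_tissue1) / len(self.log2_reps_tissue1)
        t2 = sum(self.log2_reps_tissue2) / len(self.log2_reps_tissue2)
        return t1 - t2


@dataclass(frozen=True)
class DHSPeak:
    """A DNase I hypersensitivity site, classified by tissue sharing."""

    interval: GenomicInterval
    tissue_class: str  # tissue1_specific | tissue2_specific | shared

    def __post_init__(self) -> None:
        if self.tissue_class not in ("tissue1_specific", "tissue2_specific", "shared"):
            raise ValueError(f"bad tissue_class {self.tissue_class!r}")


@dataclass
class AssociationPair:
    """One (T-DMR, gene) association with its correlation sign class.

    ``sign_class`` is one of ``positive`` (sign(ΔM) == sign(ΔE)),
    ``negative`` (opposite signs) or ``excluded`` (|ΔE| below the fold-change
    threshold, or either difference exactly zero).  It is ``None`` until
    :func:`tdmrlink.association.classify_sign` runs.
    """

    dmr_id: str
    gene_id: str
    proximity: str  # proximal | distal
    delta_m: float
    delta_e: float
    sign_class: str | None = None


@dataclass(frozen=True)
class CoherenceRecord:
    """Sign classes of all T-DMRs associated with one multi-DMR gene."""

    gene_id: str
    signs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.signs) < 2:
            raise ValueError("coherence requires >= 2 classified pairs")
        if any(s not in ("positive", "negative") for s in self.signs):
            raise ValueError("signs must be positive/negative only")

    @property
    def n_dmrs(self) -> int:
        return len(self.signs)

    @property
    def coherence_class(self) -> str:
        if all(s == "positive" for s in self.signs):
            return "coherent_positive"
        if all(s == "negative" for s in self.signs):
            return "coherent_negative"
        return "incoherent"


@dataclass(frozen=True)
class EnrichmentResult:
    """One category's over-representation test (GO term or feature label)."""

    category: str
    name: str
    k: int  # hits in the gene set
    n: int  # gene-set size
    K: int  # hits in the background
    N: int  # background size
    p: float
    p_corrected: float
    ratio: float


@dataclass(frozen=True)
class MotifResult:
    """Enrichment of one k-mer in a target sequence set vs background."""

    kmer: str
    count_target: int
    positions_target: int
    count_bg: int
    positions_bg: int
    p: float
    q: float
    enrichment_score: float
    significant: bool
    boundary: bool = False  # background rate was exactly zero

    @property
    def has_cpg(self) -> bool:
        return "CG" in self.kmer


@dataclass(frozen=True)
class MotifClassification:
    """Regulatory role of one k-mer across the two class analyses."""

    kmer: str
    role: str  # negative | positive | dual | none

    def __post_init__(self) -> None:
        if self.role not in ("negative", "positive", "dual", "none"):
            raise ValueError(f"bad role {self.role!r}")


def expression_index(records: Sequence[ExpressionRecord]) -> dict[str, ExpressionRecord]:
    return {r.gene_id: r for r in records}
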