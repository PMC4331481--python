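"""Readers and writers for the standard formats the pipeline consumes.

Internally everything is 0-based half-open; GTF (1-based inclusive) is
converted at this boundary and nowhere else.  Tabular outputs are TSV with a
header line.  Every CLI run writes a JSON parameter manifest (including the
seed) next to its outputs; see :func:`write_manifest`.
"""

from __future__ import annotations

import json
import logging
import math
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pyranges
from pyfaidx import Fasta

from .model import ExpressionRecord, GeneModel, GenomicInterval, TDMR

logger = logging.getLogger("tdmrlink")
if not logger.handlers:  # default: warnings to stderr, configurable by the CLI
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.WARNING)


class ParseError(ValueError):
    """Malformed input line; the message names the file and line number."""


@dataclass(frozen=True)
class BedRecord:
    """One BED line: the interval plus any columns beyond the first six."""

    interval: GenomicInterval
    extra: tuple[str, ...] = ()

    @property
    def name(self) -> str | None:
        return self.extra[0] if self.extra else None


_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(path: str | Path, min_cols: int = 3) -> list[BedRecord]:
    """Read a BED3+ file (narrowPeak works with ``min_cols=10``).

    Coordinates are kept as-is (BED is already 0-based half-open).  Track,
    browser and comment lines are skipped.  Columns 4+ are preserved in
    ``extra``; column 6, when present and valid, becomes the strand.
    """
    records: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {min_cols} columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            try:
                iv = GenomicInterval(fields[0], start, end, strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(BedRecord(iv, tuple(fields[3:])))
    return records


def write_bed(path: str | Path, records: Iterable[BedRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval
            fields = [iv.chrom, str(iv.start), str(iv.end), *rec.extra]
            fh.write("\t".join(fields) + "\n")


def _gene_from_bed12(rec: BedRecord, path, lineno_hint: str) -> GeneModel | None:
    fields = (rec.interval.chrom, str(rec.interval.start), str(rec.interval.end)) + rec.extra
    if len(fields) < 12:
        raise ParseError(f"{path}: BED12 line {lineno_hint} has {len(fields)} columns")
    name, strand = fields[3], fields[5]
    if strand not in ("+", "-"):
        logger.warning("%s: gene %s has unknown strand %r; record rejected", path, name, strand)
        return None
    start = rec.interval.start
    n_blocks = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise ParseError(f"{path}: gene {name}: blockCount inconsistent with block lists")
    exons = tuple(
        GenomicInterval(rec.interval.chrom, start + off, start + off + size, strand)
        for off, size in zip(offsets, sizes)
    )
    iv = GenomicInterval(rec.interval.chrom, start, rec.interval.end, strand)
    return GeneModel(gene_id=name, interval=iv, exons=exons)


def _genes_from_gtf(path: str | Path) -> list[GeneModel]:
    df = pyranges.read_gtf(str(path), as_df=True)  # converts to 0-based half-open
    genes: list[GeneModel] = []
    for gene_id, grp in df.groupby("gene_id", sort=True):
        strand = str(grp["Strand"].iloc[0])
        if strand not in ("+", "-"):
            logger.warning("%s: gene %s has unknown strand %r; record rejected",
                           path, gene_id, strand)
            continue
        chrom = str(grp["Chromosome"].iloc[0])
        gene_rows = grp[grp["Feature"] == "gene"]
        exon_rows = grp[grp["Feature"] == "exon"]
        if len(gene_rows):
            start = int(gene_rows["Start"].iloc[0])
            end = int(gene_rows["End"].iloc[0])
        elif len(exon_rows):
            start = int(exon_rows["Start"].min())
            end = int(exon_rows["End"].max())
        else:
            continue
        exons = tuple(
            GenomicInterval(chrom, int(r.Start), int(r.End), strand)
            for r in exon_rows.itertuples()
        )
        iv = GenomicInterval(chrom, start, end, strand)
        genes.append(GeneModel(gene_id=str(gene_id), interval=iv, exons=exons))
    return genes


def read_gene_models(path: str | Path, dialect: str = "bed12") -> list[GeneModel]:
    """Read gene models from BED12 (0-based half-open) or GTF (1-based inclusive).

    Output coordinates are always internal 0-based half-open; the TSS is
    strand-resolved.  Genes with unknown strand are rejected with a warning;
    an exon outside its gene span raises.
    """
    if dialect == "bed12":
        genes = []
        for rec in read_bed(path, min_cols=12):
            g = _gene_from_bed12(rec, path, rec.extra[0] if rec.extra else "?")
            if g is not None:
                genes.append(g)
        return genes
    if dialect == "gtf":
        return _genes_from_gtf(path)
    raise ValueError(f"unknown dialect {dialect!r}; use 'bed12' or 'gtf'")


def write_gene_models_bed12(path: str | Path, genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            exons = g.exons or (iv,)
            sizes = ",".join(str(e.length) for e in exons) + ","
            offsets = ",".join(str(e.start - iv.start) for e in exons) + ","
            fh.write(
                "\t".join(
                    [iv.chrom, str(iv.start), str(iv.end), g.gene_id, "0", g.strand,
                     str(iv.start), str(iv.end), "0", str(len(exons)), sizes, offsets]
                )
                + "\n"
            )


def read_expression_table(
    path: str | Path,
    tissue1_cols: Sequence[str],
    tissue2_cols: Sequence[str],
    log_transform: bool = False,
    gene_col: str = "gene_id",
) -> list[ExpressionRecord]:
    """Read a replicate expression table (TSV with header).

    ``tissue1_cols``/``tissue2_cols`` name the replicate columns.  With
    ``log_transform`` the values are linear and are log2-transformed here;
    otherwise they are taken as already log2.  Genes with any missing
    replicate are dropped with a warning; non-positive values under
    ``log_transform`` raise.
    """
    df = pd.read_csv(path, sep="\t")
    for col in [gene_col, *tissue1_cols, *tissue2_cols]:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    records: list[ExpressionRecord] = []
    n_dropped = 0
    rep_cols = list(tissue1_cols) + list(tissue2_cols)
    for row in df.itertuples(index=False):
        vals = {c: getattr(row, c) for c in rep_cols}
        if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in vals.values()):
            n_dropped += 1
            continue
        if log_transform:
            if any(v <= 0 for v in vals.values()):
                raise ValueError(
                    f"{path}: non-positive expression for gene "
                    f"{getattr(row, gene_col)} under log transform"
                )
            vals = {c: math.log2(v) for c, v in vals.items()}
        records.append(
            ExpressionRecord(
                gene_id=str(getattr(row, gene_col)),
                log2_reps_tissue1=tuple(float(vals[c]) for c in tissue1_cols),
                log2_reps_tissue2=tuple(float(vals[c]) for c in tissue2_cols),
            )
        )
    if n_dropped:
        logger.warning("%s: dropped %d genes with missing replicate values", path, n_dropped)
    return records


def read_dmr_table(path: str | Path) -> list[TDMR]:
    """Read a T-DMR TSV: dmr_id, chrom, start, end, m_tissue1, m_tissue2."""
    df = pd.read_csv(path, sep="\t")
    dmrs = [
        TDMR(
            dmr_id=str(r.dmr_id),
            interval=GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            m_tissue1=float(r.m_tissue1),
            m_tissue2=float(r.m_tissue2),
        )
        for r in df.itertuples(index=False)
    ]
    if len({d.dmr_id for d in dmrs}) != len(dmrs):
        raise ParseError(f"{path}: duplicate dmr_id values")
    return dmrs


def write_dmr_table(path: str | Path, dmrs: Sequence[TDMR]) -> None:
    rows = [
        {
            "dmr_id": d.dmr_id,
            "chrom": d.interval.chrom,
            "start": d.interval.start,
            "end": d.interval.end,
            "m_tissue1": d.m_tissue1,
            "m_tissue2": d.m_tissue2,
            "delta_m": d.delta_m,
        }
        for d in dmrs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_enhancer_map(path: str | Path) -> pd.DataFrame:
    """Enhancer→promoter map: enhancer_chrom, enhancer_start, enhancer_end,
    target_gene_id."""
    df = pd.read_csv(path, sep="\t")
    required = {"enhancer_chrom", "enhancer_start", "enhancer_end", "target_gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_gene2go(path: str | Path) -> pd.DataFrame:
    """Gene→term map: gene_id, term_id, term_name."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "term_id", "term_name"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """bedGraph of per-position scores: chrom, start, end, score."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "score"],
    )
    return df[~df["chrom"].astype(str).str.startswith(("track", "browser"))].reset_index(drop=True)


def write_bedgraph(path: str | Path, df: pd.DataFrame) -> None:
    df[["chrom", "start", "end", "score"]].to_csv(path, sep="\t", index=False, header=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA into memory as a dict of uppercase sequences."""
    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_manifest(outdir: str | Path, params: dict) -> Path:
    """Write the run's parameter manifest (seed included) next to outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path


def intervals_to_bed_records(
    intervals: Iterable[GenomicInterval], names: Iterable[str] | None = None
) -> list[BedRecord]:
    if names is None:
        return [BedRecord(iv) for iv in intervals]
    return [BedRecord(iv, (str(n),)) for iv, n in zip(intervals, names)]
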