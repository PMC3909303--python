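"""Reading, validation and preprocessing of expression data and gene annotation.

The segmentation model consumes one :class:`ExpressionMatrix` per chromosome
arm, with genes ordered by their annotated transcription start coordinate.
This module provides the preprocessing pipeline that produces those matrices
from probe-level data (probeset collapsing, replicate quality control and
averaging) together with readers for the tab-separated expression format and
BED/GFF gene annotation, and the start-to-start intergenic region helper used
by the downstream interval statistics.

All internal genomic coordinates are 0-based half-open.  BED input is taken
as-is; GFF3 is converted from 1-based inclusive on read.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("coexseg")

__all__ = [
    "ExpressionMatrix",
    "GeneAnnotation",
    "IntervalSet",
    "collapse_probesets",
    "split_replicates",
    "qc_filter_tissues",
    "average_replicates",
    "order_genes_by_start",
    "intergenic_regions",
    "read_gene_bed",
    "read_gene_gff3",
    "read_bed_intervals",
    "write_bed_intervals",
]

_VALID_STRANDS = {"+", "-"}


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: arm, transcription start coordinate (0-based) and strand."""

    gene_id: str
    arm: str
    start: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"gene {self.gene_id}: start must be >= 0, got {self.start}")
        if self.strand not in _VALID_STRANDS and self.strand != ".":
            raise ValueError(f"gene {self.gene_id}: strand must be +, - or '.', got {self.strand!r}")


@dataclass
class ExpressionMatrix:
    """Normalized log-scale expression for the ordered genes of one arm.

    ``values[i, j]`` is the expression of ``genes[i]`` in ``tissues[j]`` — the
    x_i of the segment model.  Gene order is the annotated transcription-start
    order along the arm.
    """

    arm_id: str
    genes: list[str]
    tissues: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x tissues matrix")
        if len(self.genes) < 1 or len(self.tissues) < 1:
            raise ValueError("need at least one gene and one tissue")
        if self.values.shape != (len(self.genes), len(self.tissues)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.genes)} genes x {len(self.tissues)} tissues"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no missing values)")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_tissues(self) -> int:
        return len(self.tissues)

    def to_tsv(self, path) -> None:
        """Write the matrix as TSV with full float precision (round-trip safe)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("gene_id\t" + "\t".join(self.tissues) + "\n")
            for g, row in zip(self.genes, self.values):
                fh.write(g + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path, arm_id: str = "all") -> "ExpressionMatrix":
        df = read_expression_tsv(path)
        return cls(arm_id, list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class IntervalSet:
    """Genomic intervals (arm, begin, end) with a role tag.

    Used for ChIP peaks, physical interaction domains, intergenic and
    intersegment regions, and boundary masking windows.
    """

    intervals: list[tuple[str, int, int]]
    label: str = ""

    def __post_init__(self) -> None:
        # zero-length intervals are tolerated (tied transcription starts can
        # produce them); negative lengths are not.
        for arm, begin, end in self.intervals:
            if end < begin:
                raise ValueError(f"interval ({arm}, {begin}, {end}): end must be >= begin")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def total_bases(self) -> int:
        return sum(e - b for _, b, e in self.intervals)

    def lengths(self) -> np.ndarray:
        return np.array([e - b for _, b, e in self.intervals], dtype=int)


# ---------------------------------------------------------------------------
# Expression preprocessing
# ---------------------------------------------------------------------------

def read_expression_tsv(path) -> pd.DataFrame:
    """Read a genes x columns expression TSV (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str}, float_precision="round_trip")
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no expression columns found")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression value: {exc}") from exc
    return df


def collapse_probesets(probe_values: pd.DataFrame, probe_map: Mapping[str, str]) -> pd.DataFrame:
    """Collapse probe-level values to gene level by the per-gene median.

    Probes absent from ``probe_map`` are dropped.  Each value of the result is
    the median over the gene's probesets in that tissue.
    """
    mapped = probe_values.loc[[p for p in probe_values.index if p in probe_map]]
    if mapped.empty:
        raise ValueError("no probe maps to any gene: unusable probe map")
    genes = pd.Series({p: probe_map[p] for p in mapped.index}, name="gene")
    out = mapped.groupby(genes).median()
    out.index.name = "gene_id"
    return out


def split_replicates(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Group replicate columns ``tissue.rep`` by tissue.

    A column without a ``.`` suffix is a single-replicate tissue.  Column
    order is preserved within and across tissues.
    """
    groups: dict[str, list[str]] = {}
    for col in df.columns:
        tissue = col.rsplit(".", 1)[0] if "." in col else col
        groups.setdefault(tissue, []).append(col)
    return {t: df[cols] for t, cols in groups.items()}


def qc_filter_tissues(
    replicates: Mapping[str, pd.DataFrame], threshold: float = 0.98
) -> list[str]:
    """Keep tissues whose every replicate pair has Pearson r >= threshold.

    Correlation is computed across genes.  A replicate with zero variance
    makes the correlation undefined; such tissues are dropped with a warning.
    Tissues with a single replicate pass trivially (no pair to test).
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    kept: list[str] = []
    for tissue, reps in replicates.items():
        arr = np.asarray(reps, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"tissue {tissue}: replicate table must be 2-D")
        n_rep = arr.shape[1]
        if n_rep == 1:
            kept.append(tissue)
            continue
        if np.any(np.std(arr, axis=0) == 0):
            log.warning("tissue %s: zero-variance replicate, correlation undefined; dropped", tissue)
            continue
        corr = np.corrcoef(arr.T)
        pair_min = np.min(corr[np.triu_indices(n_rep, k=1)])
        if pair_min >= threshold:
            kept.append(tissue)
        else:
            log.info("tissue %s dropped: min replicate correlation %.4f < %.4f", tissue, pair_min, threshold)
    return kept


def average_replicates(replicates: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per gene and tissue, arithmetic mean over the tissue's replicates."""
    cols = {t: np.asarray(reps, dtype=float).mean(axis=1) for t, reps in replicates.items()}
    index = next(iter(replicates.values())).index
    return pd.DataFrame(cols, index=index)


def preprocess_expression(df: pd.DataFrame, qc_threshold: float = 0.98) -> pd.DataFrame:
    """Replicate QC then averaging; identity on single-replicate input."""
    reps = split_replicates(df)
    kept = qc_filter_tissues(reps, threshold=qc_threshold)
    if not kept:
        raise ValueError("no tissue passed replicate QC")
    return average_replicates({t: reps[t] for t in kept})


# ---------------------------------------------------------------------------
# Annotation, ordering, intergenic regions
# ---------------------------------------------------------------------------

def order_genes_by_start(
    annotations: Iterable[GeneAnnotation], matrix: pd.DataFrame
) -> list[ExpressionMatrix]:
    """Split a genes x tissues table into per-arm matrices ordered by start.

    Ties on start are broken by gene identifier (lexicographic).  Matrix genes
    without an annotation are dropped with a warning; annotated genes absent
    from the matrix are ignored.
    """
    ann = {a.gene_id: a for a in annotations}
    missing = [g for g in matrix.index if g not in ann]
    if missing:
        log.warning("%d matrix genes lack annotation and were dropped (e.g. %s)", len(missing), missing[0])
    by_arm: dict[str, list[GeneAnnotation]] = {}
    for g in matrix.index:
        a = ann.get(g)
        if a is not None:
            by_arm.setdefault(a.arm, []).append(a)
    out = []
    for arm in sorted(by_arm):
        ordered = sorted(by_arm[arm], key=lambda a: (a.start, a.gene_id))
        genes = [a.gene_id for a in ordered]
        out.append(
            ExpressionMatrix(arm, genes, list(matrix.columns), matrix.loc[genes].to_numpy(dtype=float))
        )
    return out


def intergenic_regions(annotations: Sequence[GeneAnnotation]) -> IntervalSet:
    """Start-to-start regions between adjacent genes of one arm.

    n genes yield exactly n-1 regions; region length is the difference of the
    adjacent transcription start coordinates (not end-to-start).  Tied starts
    give a zero-length region, kept (to preserve the n-1 count) with a warning.
    """
    if len(annotations) < 2:
        raise ValueError("need at least 2 genes to form intergenic regions")
    arms = {a.arm for a in annotations}
    if len(arms) != 1:
        raise ValueError(f"annotations span multiple arms: {sorted(arms)}")
    ordered = sorted(annotations, key=lambda a: (a.start, a.gene_id))
    intervals = []
    for a, b in zip(ordered[:-1], ordered[1:]):
        if b.start == a.start:
            log.warning("genes %s and %s share start %d: zero-length intergenic region",
                        a.gene_id, b.gene_id, a.start)
        intervals.append((a.arm, a.start, b.start))
    return IntervalSet(intervals, label="intergenic")


# ---------------------------------------------------------------------------
# BED / GFF readers
# ---------------------------------------------------------------------------

def _tss(start: int, end: int, strand: str) -> int:
    # transcription start: left edge for +, right edge for - (0-based)
    return start if strand != "-" else end - 1


def read_gene_bed(path) -> list[GeneAnnotation]:
    """Read gene annotation from BED6 (name column = gene id).

    The transcription start is the strand-appropriate edge of the interval:
    chromStart for + genes, chromEnd-1 for - genes.
    """
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 requires 6 fields, got {len(parts)}")
            chrom, start, end, name, _score, strand = parts[:6]
            try:
                s, e = int(start), int(end)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates {start!r}/{end!r}") from None
            if e <= s:
                raise ValueError(f"{path}:{lineno}: end {e} <= start {s}")
            out.append(GeneAnnotation(name, chrom, _tss(s, e, strand), strand))
    return out


def read_gene_gff3(path) -> list[GeneAnnotation]:
    """Read gene lines from GFF3 (1-based inclusive, converted on read)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: GFF3 requires 9 fields, got {len(parts)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            try:
                s1, e1 = int(start), int(end)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates {start!r}/{end!r}") from None
            gene_id = None
            for kv in attrs.split(";"):
                kv = kv.strip()
                if kv.startswith(("ID=", "gene_id=")):
                    gene_id = kv.split("=", 1)[1]
                    break
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: gene line lacks ID attribute")
            s, e = s1 - 1, e1  # to 0-based half-open
            out.append(GeneAnnotation(gene_id, chrom, _tss(s, e, strand), strand))
    return out


def read_bed_intervals(path, label: str = "") -> IntervalSet:
    """Read BED3+ intervals (peaks, domains, masks)."""
    intervals = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED requires >= 3 fields, got {len(parts)}")
            try:
                b, e = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if e <= b:
                raise ValueError(f"{path}:{lineno}: end {e} <= start {b}")
            intervals.append((parts[0], b, e))
    return IntervalSet(intervals, label=label)


def write_bed_intervals(path, intervals: IntervalSet, names: Sequence[str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, (arm, b, e) in enumerate(intervals):
            name = names[i] if names is not None else f"{intervals.label or 'region'}_{i}"
            fh.write(f"{arm}\t{b}\t{e}\t{name}\n")
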