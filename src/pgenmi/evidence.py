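"""Construction of binary cis-regulatory evidence from peak intervals.

Six encoding strategies turn TF ChIP-seq peaks, histone-mark ChIP-seq peaks
(two stages x two replicates), and ATAC-seq peaks (two stages) into a binary
genes x (TF, mark-change) matrix:

* ``DiffMark`` — TFBS overlapping a stage-exclusive ("dynamic") histone-mark
  peak, within distance d of the TSS; 8 columns per TF (4 marks x up/down).
* ``DiffMarkAggr`` — per-direction disjunction of the DiffMark columns;
  2 columns per TF.
* ``PresMark`` — TFBS overlapping a mark peak from either stage; 4 per TF.
* ``DiffAcc`` / ``PresAcc`` — as DiffMark/PresMark with ATAC peaks in place
  of histone marks (2 resp. 1 column per TF).
* ``TFBSonly`` — any TFBS within the window; 1 column per TF.

All coordinates are 0-based half-open (BED convention); overlap means >= 1
shared base.  The gene window is [tss - d, tss + d), strand used only to
locate the TSS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .containers import (
    DEPValueVector,
    EvidenceColumnKey,
    EvidenceMatrix,
    HISTONE_MARKS,
)

logger = logging.getLogger(__name__)

STRATEGIES = ("DiffMark", "DiffMarkAggr", "PresMark", "DiffAcc", "PresAcc", "TFBSonly")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (_norm_chrom(iv.chrom), iv.start, iv.end))


@dataclass
class PeakSet:
    """A labelled, coordinate-sorted set of peaks (one assay/mark/TF)."""

    label: str
    intervals: list[GenomicInterval]
    stage: str = "none"  # {"early", "late", "none"}
    replicate: Optional[str] = None

    def __post_init__(self) -> None:
        if self.stage not in ("early", "late", "none"):
            raise ValueError(f"unknown stage {self.stage!r}")
        self.intervals = sort_intervals(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class GeneAnnotation:
    """Gene coordinates; TSS is body_start on '+' and body_end on '-'."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    body_start: int
    body_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.body_start < self.body_end:
            raise ValueError("body_start must be < body_end")


@dataclass
class DynamicMarkSet:
    """Stage-exclusive peaks for one mark and one direction of change:
    'down' = present only in the early stage, 'up' = only in the late stage."""

    mark: str
    direction: str  # {"up", "down"}
    intervals: list[GenomicInterval]

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        self.intervals = sort_intervals(self.intervals)


@dataclass
class EvidenceConfig:
    """Strategy plus the TSS window half-width d (bases)."""

    strategy: str = "DiffMark"
    distance_d: int = 50_000

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}"
            )
        if self.distance_d <= 0:
            raise ValueError("distance_d must be positive")


# ---------------------------------------------------------------------------
# interval machinery


def _trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    by_chrom: dict[str, IntervalTree] = {}
    for iv in intervals:
        by_chrom.setdefault(_norm_chrom(iv.chrom), IntervalTree()).addi(
            iv.start, iv.end, iv
        )
    return by_chrom

def _overlaps_any(trees: Mapping[str, IntervalTree], iv: GenomicInterval) -> bool:
    tree = trees.get(_norm_chrom(iv.chrom))
    return bool(tree is not None and tree.overlap(iv.start, iv.end))


def _overlapping(trees: Mapping[str, IntervalTree], chrom: str, start: int, end: int):
    tree = trees.get(_norm_chrom(chrom))
    if tree is None:
        return []
    return [node.data for node in tree.overlap(start, end)]


def gene_window(gene: GeneAnnotation, distance_d: int) -> tuple[int, int]:
    """Half-open TSS-centered window [tss - d, tss + d), floored at 0."""
    return max(0, gene.tss - distance_d), gene.tss + distance_d


# ---------------------------------------------------------------------------
# dynamic mark calling


def call_dynamic_marks(
    early_rep1: PeakSet,
    early_rep2: PeakSet,
    late_rep1: PeakSet,
    late_rep2: PeakSet,
) -> tuple[DynamicMarkSet, DynamicMarkSet]:
    """Split one mark's peaks into stage-exclusive 'up' and 'down' sets.

    A stage-consistent peak is a rep1 interval overlapping (>= 1 bp) any rep2
    interval of the same stage, reported with rep1 coordinates.  'down' keeps
    the early-consistent peaks with zero overlap against both late replicates;
    'up' is symmetric.  Returns (up, down), each coordinate-sorted.
    """
    labels = {early_rep1.label, early_rep2.label, late_rep1.label, late_rep2.label}
    if len(labels) != 1:
        raise ValueError(f"all four peak sets must carry the same mark label, got {sorted(labels)}")
    mark = early_rep1.label

    def consistent(rep1: PeakSet, rep2: PeakSet) -> list[GenomicInterval]:
        t2 = _trees(rep2.intervals)
        return [iv for iv in rep1.intervals if _overlaps_any(t2, iv)]

    early_cons = consistent(early_rep1, early_rep2)
    late_cons = consistent(late_rep1, late_rep2)
    late_all = _trees(late_rep1.intervals + late_rep2.intervals)
    early_all = _trees(early_rep1.intervals + early_rep2.intervals)

    down = [iv for iv in early_cons if not _overlaps_any(late_all, iv)]
    up = [iv for iv in late_cons if not _overlaps_any(early_all, iv)]
    return (
        DynamicMarkSet(mark=mark, direction="up", intervals=up),
        DynamicMarkSet(mark=mark, direction="down", intervals=down),
    )


def call_dynamic_single_replicate(
    early: PeakSet, late: PeakSet, mark: str = "ATAC"
) -> tuple[DynamicMarkSet, DynamicMarkSet]:
    """Stage-exclusive peaks from one profile per stage (ATAC-style)."""
    late_t = _trees(late.intervals)
    early_t = _trees(early.intervals)
    down = [iv for iv in early.intervals if not _overlaps_any(late_t, iv)]
    up = [iv for iv in late.intervals if not _overlaps_any(early_t, iv)]
    return (
        DynamicMarkSet(mark=mark, direction="up", intervals=up),
        DynamicMarkSet(mark=mark, direction="down", intervals=down),
    )


# ---------------------------------------------------------------------------
# strategy builders


def _clip_len(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def _directional_evidence(
    tf_peaks: Mapping[str, PeakSet],
    dyn_by_mark: Mapping[str, dict[str, DynamicMarkSet]],
    genes: Sequence[GeneAnnotation],
    cfg: EvidenceConfig,
    marks: Sequence[str],
) -> EvidenceMatrix:
    """Shared core of DiffMark and DiffAcc.

    ``dyn_by_mark[mark][direction]`` holds the dynamic interval sets.  For
    each (gene, TF, mark) where both directions fire, only the direction with
    the larger total TFBS-dynamic overlap (clipped to the gene window) is
    kept; ties go to 'up'.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    tfs = sorted(tf_peaks)
    columns = [
        EvidenceColumnKey(tf, mark, direction)
        for tf in tfs
        for mark in marks
        for direction in ("up", "down")
    ]
    col_pos = {c: i for i, c in enumerate(columns)}
    values = np.zeros((len(genes), len(columns)), dtype=np.uint8)

    dyn_trees = {
        (mark, d): _trees(dyn_by_mark[mark][d].intervals)
        for mark in marks
        for d in ("up", "down")
    }
    for tf in tfs:
        peaks = tf_peaks[tf]
        if len(peaks) == 0:
            logger.warning("TF %s has no peaks; its columns stay all-zero", tf)
        # TFBS flagged by each dynamic set
        flagged: dict[tuple[str, str], list[GenomicInterval]] = {}
        for key, trees in dyn_trees.items():
            flagged[key] = [iv for iv in peaks.intervals if _overlaps_any(trees, iv)]
        flagged_trees = {key: _trees(ivs) for key, ivs in flagged.items()}

        for gi, gene in enumerate(genes):
            w0, w1 = gene_window(gene, cfg.distance_d)
            for mark in marks:
                hits = {
                    d: _overlapping(flagged_trees[(mark, d)], gene.chrom, w0, w1)
                    for d in ("up", "down")
                }
                fired = [d for d in ("up", "down") if hits[d]]
                if len(fired) == 2:
                    # conflict: keep the direction with the largest change,
                    # measured as total TFBS-dynamic overlap inside the window
                    scores = {}
                    for d in ("up", "down"):
                        total = 0
                        for tfbs in hits[d]:
                            for dyn in _overlapping(
                                dyn_trees[(mark, d)], tfbs.chrom, tfbs.start, tfbs.end
                            ):
                                seg0 = max(tfbs.start, dyn.start, w0)
                                seg1 = min(tfbs.end, dyn.end, w1)
                                total += max(0, seg1 - seg0)
                        scores[d] = total
                    keep = "up" if scores["up"] >= scores["down"] else "down"
                    logger.debug(
                        "direction conflict at gene=%s tf=%s mark=%s "
                        "(up=%d bp, down=%d bp) -> %s",
                        gene.gene_id, tf, mark, scores["up"], scores["down"], keep,
                    )
                    fired = [keep]
                for d in fired:
                    values[gi, col_pos[EvidenceColumnKey(tf, mark, d)]] = 1

    return EvidenceMatrix([g.gene_id for g in genes], columns, values)


def build_diffmark(
    tf_peaks: Mapping[str, PeakSet],
    dynmarks: Sequence[DynamicMarkSet],
    genes: Sequence[GeneAnnotation],
    cfg: EvidenceConfig,
) -> EvidenceMatrix:
    """DiffMark: TFBS overlapping a dynamic histone-mark peak within the gene
    window; 2 directions x |marks| columns per TF (8 for the 4 marks)."""
    dyn_by_mark: dict[str, dict[str, DynamicMarkSet]] = {}
    for dm in dynmarks:
        dyn_by_mark.setdefault(dm.mark, {})[dm.direction] = dm
    marks = [m for m in HISTONE_MARKS if m in dyn_by_mark] or sorted(dyn_by_mark)
    for mark in marks:
        for d in ("up", "down"):
            dyn_by_mark[mark].setdefault(d, DynamicMarkSet(mark, d, []))
    return _directional_evidence(tf_peaks, dyn_by_mark, genes, cfg, marks)


def build_diffmarkaggr(diffmark_matrix: EvidenceMatrix) -> EvidenceMatrix:
    """Per-direction disjunction over marks: 2 columns per TF (ANY-up/down)."""
    tfs = diffmark_matrix.tfs
    columns = [
        EvidenceColumnKey(tf, "ANY", direction)
        for tf in tfs
        for direction in ("up", "down")
    ]
    values = np.zeros((diffmark_matrix.n_genes, len(columns)), dtype=np.uint8)
    for j, key in enumerate(columns):
        src = [
            i
            for i, c in enumerate(diffmark_matrix.columns)
            if c.tf == key.tf and c.direction == key.direction
        ]
        if src:
            values[:, j] = diffmark_matrix.values[:, src].max(axis=1)
    return EvidenceMatrix(diffmark_matrix.gene_ids, columns, values)


def _presence_evidence(
    tf_peaks: Mapping[str, PeakSet],
    peaks_by_mark: Mapping[str, Sequence[PeakSet]],
    genes: Sequence[GeneAnnotation],
    cfg: EvidenceConfig,
    marks: Sequence[str],
) -> EvidenceMatrix:
    """Shared core of PresMark/PresAcc: bit = 1 iff a TFBS inside the gene
    window overlaps any peak of the mark from any stage/replicate."""
    if not genes:
        raise ValueError("gene list must be non-empty")
    tfs = sorted(tf_peaks)
    columns = [EvidenceColumnKey(tf, mark, "present") for tf in tfs for mark in marks]
    values = np.zeros((len(genes), len(columns)), dtype=np.uint8)
    mark_trees = {
        mark: _trees([iv for ps in peaks_by_mark[mark] for iv in ps.intervals])
        for mark in marks
    }
    j = 0
    for tf in tfs:
        peaks = tf_peaks[tf]
        if len(peaks) == 0:
            logger.warning("TF %s has no peaks; its columns stay all-zero", tf)
        for mark in marks:
            flagged = _trees(
                [iv for iv in peaks.intervals if _overlaps_any(mark_trees[mark], iv)]
            )
            for gi, gene in enumerate(genes):
                w0, w1 = gene_window(gene, cfg.distance_d)
                if _overlapping(flagged, gene.chrom, w0, w1):
                    values[gi, j] = 1
            j += 1
    return EvidenceMatrix([g.gene_id for g in genes], columns, values)


def build_presmark(
    tf_peaks: Mapping[str, PeakSet],
    mark_peaks_by_stage: Mapping[str, Sequence[PeakSet]],
    genes: Sequence[GeneAnnotation],
    cfg: EvidenceConfig,
) -> EvidenceMatrix:
    """PresMark: TFBS flagged by a mark peak from either stage; 1 column per
    (TF, mark)."""
    marks = [m for m in HISTONE_MARKS if m in mark_peaks_by_stage] or sorted(
        mark_peaks_by_stage
    )
    return _presence_evidence(tf_peaks, mark_peaks_by_stage, genes, cfg, marks)


def build_diffacc(
    tf_peaks: Mapping[str, PeakSet],
    atac_by_stage: Mapping[str, PeakSet],
    genes: Sequence[GeneAnnotation],
    cfg: EvidenceConfig,
) -> EvidenceMatrix:
    """DiffAcc: stage-exclusive ATAC peaks in place of dynamic histone marks;
    2 columns per TF."""
    up, down = call_dynamic_single_replicate(
        atac_by_stage["early"], atac_by_stage["late"], mark="ATAC"
    )
    return _directional_evidence(
        tf_peaks, {"ATAC": {"up": up, "down": down}}, genes, cfg, ["ATAC"]
    )


def build_presacc(
    tf_peaks: Mapping[str, PeakSet],
    atac_by_stage: Mapping[str, PeakSet],
    genes: Sequence[GeneAnnotation],
    cfg: EvidenceConfig,
) -> EvidenceMatrix:
    """PresAcc: TFBS overlapping an ATAC peak from either stage; 1 column/TF."""
    return _presence_evidence(
        tf_peaks,
        {"ATAC": [atac_by_stage["early"], atac_by_stage["late"]]},
        genes,
        cfg,
        ["ATAC"],
    )


def build_tfbs_only(
    tf_peaks: Mapping[str, PeakSet],
    genes: Sequence[GeneAnnotation],
    cfg: EvidenceConfig,
) -> EvidenceMatrix:
    """TFBS-only baseline: any binding site within the window; 1 column/TF."""
    if not genes:
        raise ValueError("gene list must be non-empty")
    tfs = sorted(tf_peaks)
    columns = [EvidenceColumnKey(tf, "TFBS", "present") for tf in tfs]
    values = np.zeros((len(genes), len(columns)), dtype=np.uint8)
    for j, tf in enumerate(tfs):
        trees = _trees(tf_peaks[tf].intervals)
        for gi, gene in enumerate(genes):
            w0, w1 = gene_window(gene, cfg.distance_d)
            if _overlapping(trees, gene.chrom, w0, w1):
                values[gi, j] = 1
    return EvidenceMatrix([g.gene_id for g in genes], columns, values)


# ---------------------------------------------------------------------------
# DE p-value transformation


def transform_de_pvalues(de_table: pd.DataFrame, mode: str) -> DEPValueVector:
    """Directionalize DE p-values for the up- or down-analysis.

    In down-mode, genes with fold change > 1 (log2fc > 0) get p -> 1 - p so
    only downregulated genes retain small p-values; up-mode is symmetric.
    Genes with fold change exactly 1 (log2fc = 0) are left unchanged in both
    modes.  Rows missing log2fc or pval are dropped with a logged count.
    """
    if mode not in ("up", "down"):
        raise ValueError(f"mode must be 'up' or 'down', got {mode!r}")
    required = {"gene_id", "log2fc", "pval"}
    missing_cols = required - set(de_table.columns)
    if missing_cols:
        raise ValueError(f"DE table lacks columns: {sorted(missing_cols)}")
    table = de_table[["gene_id", "log2fc", "pval"]].copy()
    n_before = len(table)
    table = table.dropna(subset=["log2fc", "pval"])
    n_dropped = n_before - len(table)
    if n_dropped:
        logger.info("dropped %d genes with missing fold change or p-value", n_dropped)
    p = table["pval"].to_numpy(dtype=float)
    lfc = table["log2fc"].to_numpy(dtype=float)
    flip = (lfc > 0) if mode == "down" else (lfc < 0)
    p = np.where(flip, 1.0 - p, p)
    return DEPValueVector(table["gene_id"].tolist(), p, mode=mode)
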