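"""Core in-memory containers shared across the package.

The central objects are :class:`EvidenceMatrix` — a genes x binary-evidence
matrix whose columns are keyed by (TF, mark-change) pairs — and
:class:`DEPValueVector`, the per-gene differential-expression p-values after
the directional transformation.  Both are thin, validated wrappers around
numpy arrays; pandas interop is provided via ``to_frame``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

#: floor applied to p-values of exactly 0 reported by upstream DE tools
PVALUE_FLOOR = 1e-12

#: the four histone marks profiled in the differentiation time course
HISTONE_MARKS = ("H3K27ac", "H3K4me1", "H3K4me3", "H3K27me3")

#: valid direction labels for an evidence column
DIRECTIONS = ("up", "down", "present")


class EvidenceColumnKey(NamedTuple):
    """Identity of one binary evidence column: TF, mark and direction.

    ``mark`` is the assay/mark label (histone mark, ``ATAC`` or ``TFBS``);
    ``direction`` is ``up``/``down`` for dynamic (stage-exclusive) evidence
    and ``present`` for presence-style encodings.
    """

    tf: str
    mark: str
    direction: str

    @property
    def name(self) -> str:
        return f"TF={self.tf};M={self.mark};D={self.direction}"

    @property
    def mark_change(self) -> str:
        """Mark-change label, e.g. ``H3K27ac-up`` — the 'm' index of w_tm."""
        if self.direction == "present":
            return self.mark
        return f"{self.mark}-{self.direction}"

    @classmethod
    def parse(cls, name: str) -> "EvidenceColumnKey":
        try:
            parts = dict(p.split("=", 1) for p in name.split(";"))
            key = cls(tf=parts["TF"], mark=parts["M"], direction=parts["D"])
        except (KeyError, ValueError) as exc:
            raise ValueError(f"malformed evidence column name {name!r}") from exc
        if key.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {key.direction!r} in {name!r}")
        return key


@dataclass
class EvidenceMatrix:
    """Binary cis-regulatory evidence, one row per gene, one column per
    (TF, mark-change) pair.

    Entry (g, c) is 1 iff a binding site for column c's TF, supported by that
    column's mark-change, lies within the configured distance of gene g's TSS.
    """

    gene_ids: list[str]
    columns: list[EvidenceColumnKey]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.columns = [
            c if isinstance(c, EvidenceColumnKey) else EvidenceColumnKey(*c)
            for c in self.columns
        ]
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n_g, n_c = self.values.shape
        if n_g != len(self.gene_ids):
            raise ValueError(
                f"{len(self.gene_ids)} gene ids but {n_g} matrix rows"
            )
        if n_c != len(self.columns):
            raise ValueError(
                f"{len(self.columns)} column keys but {n_c} matrix columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("evidence column keys must be unique")
        bad = (self.values != 0) & (self.values != 1)
        if bad.any():
            raise ValueError("evidence entries must be 0 or 1")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def tfs(self) -> list[str]:
        """TF names in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.columns:
            seen.setdefault(c.tf, None)
        return list(seen)

    @property
    def mark_changes(self) -> list[str]:
        """Mark-change labels in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.columns:
            seen.setdefault(c.mark_change, None)
        return list(seen)

    def column_indices_for_tf(self, tf: str) -> np.ndarray:
        idx = [i for i, c in enumerate(self.columns) if c.tf == tf]
        if not idx:
            raise KeyError(
                f"unknown TF {tf!r}; known TFs: {', '.join(self.tfs)}"
            )
        return np.asarray(idx, dtype=np.intp)

    def zero_tf(self, tf: str) -> "EvidenceMatrix":
        """Copy with every evidence column of ``tf`` set to all-zero."""
        idx = self.column_indices_for_tf(tf)
        values = self.values.copy()
        values[:, idx] = 0
        return EvidenceMatrix(self.gene_ids, list(self.columns), values)

    def take(self, indices: Sequence[int]) -> "EvidenceMatrix":
        """Row subset (gene subset) in the given order."""
        idx = np.asarray(indices, dtype=np.intp)
        return EvidenceMatrix(
            [self.gene_ids[i] for i in idx], list(self.columns), self.values[idx]
        )

    def select_columns(self, indices: Sequence[int]) -> "EvidenceMatrix":
        """Column subset in the given order."""
        idx = np.asarray(indices, dtype=np.intp)
        return EvidenceMatrix(
            list(self.gene_ids), [self.columns[i] for i in idx], self.values[:, idx]
        )

    def hstack(self, other: "EvidenceMatrix") -> "EvidenceMatrix":
        """Concatenate columns of two matrices over the same gene universe."""
        if self.gene_ids != other.gene_ids:
            raise ValueError("matrices must share the same gene universe")
        return EvidenceMatrix(
            list(self.gene_ids),
            list(self.columns) + list(other.columns),
            np.hstack([self.values, other.values]),
        )

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.gene_ids, name="GENE"),
            columns=[c.name for c in self.columns],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EvidenceMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.columns == other.columns
            and np.array_equal(self.values, other.values)
        )


def clamp_pvalues(pvals: np.ndarray, floor: float = PVALUE_FLOOR) -> np.ndarray:
    """Clamp p-values of exactly 0 to the floor; validate the (0, 1] range."""
    p = np.asarray(pvals, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and within [0, 1]")
    return np.where(p < floor, floor, p)


@dataclass
class DEPValueVector:
    """Per-gene DE p-values after the directional (up/down) transformation."""

    gene_ids: list[str]
    pvals: np.ndarray
    mode: str = "raw"  # {"up", "down", "raw"}

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        if self.mode not in ("up", "down", "raw"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.pvals = clamp_pvalues(self.pvals)
        if len(self.gene_ids) != self.pvals.shape[0]:
            raise ValueError("gene ids and p-values differ in length")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def take(self, indices: Sequence[int]) -> "DEPValueVector":
        idx = np.asarray(indices, dtype=np.intp)
        return DEPValueVector(
            [self.gene_ids[i] for i in idx], self.pvals[idx], mode=self.mode
        )


def check_aligned(matrix: EvidenceMatrix, pvals: DEPValueVector) -> None:
    """Require identical gene order between an evidence matrix and p-values."""
    if matrix.gene_ids != pvals.gene_ids:
        raise ValueError(
            "evidence matrix and p-value vector must list the same genes in "
            f"the same order ({matrix.n_genes} vs {len(pvals)} genes)"
        )


def diffmark_layout(
    tfs: Sequence[str], marks: Iterable[str] = HISTONE_MARKS
) -> list[EvidenceColumnKey]:
    """Column layout of the DiffMark strategy: per TF, one column per
    (mark, direction) pair — 8 columns per TF for the 4 histone marks."""
    return [
        EvidenceColumnKey(tf, mark, direction)
        for tf in tfs
        for mark in marks
        for direction in ("up", "down")
    ]
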