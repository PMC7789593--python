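"""Readers and writers for the package's on-disk formats.

Interval files use BED conventions (0-based half-open); MACS2 narrowPeak is
the 10-column BED6+4 dialect with -log10(q) in column 9.  The model input
("evidence file") is a TSV with header ``GENE  PVAL  <col> ...`` where each
evidence column is named ``TF=<tf>;M=<mark>;D=<up|down|present>`` and
entries are strictly 0/1.  Writers prepend a comment header carrying the
tool version, the seed, and a hash of the configuration so any output can
be traced back to its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import DEPValueVector, EvidenceColumnKey, EvidenceMatrix
from .evidence import GeneAnnotation, GenomicInterval, PeakSet
from .model import FitResult, FwParams

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# peak files


def _parse_interval_line(
    line: str, lineno: int, path: str, qvalue_min: Optional[float]
) -> Optional[GenomicInterval]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
    score = None
    if len(fields) >= 10:  # narrowPeak: signal, -log10(p), -log10(q), summit
        try:
            qval = float(fields[8])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed q-value column") from exc
        score = qval
        if qvalue_min is not None and qval < qvalue_min:
            return None
    elif qvalue_min is not None:
        raise ValueError(
            f"{path}: q-value filtering requires 10-column narrowPeak input"
        )
    try:
        return GenomicInterval(chrom=chrom, start=start, end=end, score=score)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: {exc}") from exc


def read_narrowpeak(
    path: Union[str, Path],
    qvalue_min: Optional[float] = None,
    label: Optional[str] = None,
    stage: str = "none",
    replicate: Optional[str] = None,
) -> PeakSet:
    """Read a BED3/BED6 or MACS2 narrowPeak file into a sorted PeakSet.

    ``qvalue_min`` filters on the -log10(q) column (narrowPeak only).
    """
    path = Path(path)
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            iv = _parse_interval_line(line, lineno, str(path), qvalue_min)
            if iv is not None:
                intervals.append(iv)
    if not intervals:
        logger.warning("peak file %s is empty", path)
    return PeakSet(
        label=label if label is not None else path.stem,
        intervals=intervals,
        stage=stage,
        replicate=replicate,
    )


read_bed = read_narrowpeak  # BED3/BED6 share the reader


def write_narrowpeak(peaks: PeakSet, path: Union[str, Path]) -> None:
    """Write a PeakSet as 10-column narrowPeak (score column carries the
    -log10(q) when present; placeholders elsewhere)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(peaks.intervals):
            q = iv.score if iv.score is not None else -1
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{peaks.label}_{i}\t0\t.\t"
                f"0\t-1\t{q:g}\t-1\n"
            )


def write_bed(peaks: PeakSet, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for iv in peaks.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# gene annotation


_ANNOT_COLS = ["gene_id", "chrom", "strand", "tss", "start", "end"]


def read_gene_annotation(path: Union[str, Path]) -> list[GeneAnnotation]:
    """TSV with columns gene_id, chrom, strand, tss, start, end
    (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_ANNOT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: annotation lacks columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"{path}: duplicate gene ids {dups[:5]}")
    return [
        GeneAnnotation(
            gene_id=str(r.gene_id), chrom=str(r.chrom), strand=str(r.strand),
            tss=int(r.tss), body_start=int(r.start), body_end=int(r.end),
        )
        for r in df.itertuples()
    ]


def write_gene_annotation(genes: Sequence[GeneAnnotation], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ANNOT_COLS) + "\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t"
                f"{g.body_start}\t{g.body_end}\n"
            )


def genes_from_gtf(path: Union[str, Path]) -> list[GeneAnnotation]:
    """Extract gene records from a GTF file (1-based inclusive on disk,
    converted to 0-based half-open)."""
    genes = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            chrom, start, end, strand, attrs = (
                fields[0], int(fields[3]) - 1, int(fields[4]), fields[6], fields[8],
            )
            gene_id = None
            for attr in attrs.split(";"):
                attr = attr.strip()
                if attr.startswith("gene_id"):
                    gene_id = attr.split(None, 1)[1].strip('"')
                    break
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: gene record lacks gene_id")
            if gene_id in seen:
                continue
            seen.add(gene_id)
            tss = start if strand == "+" else end
            genes.append(
                GeneAnnotation(
                    gene_id=gene_id, chrom=chrom, strand=strand, tss=tss,
                    body_start=start, body_end=end,
                )
            )
    return genes


# ---------------------------------------------------------------------------
# DE tables


def read_de_table(path: Union[str, Path]) -> pd.DataFrame:
    """Per-gene DE results: gene_id, log2fc, pval (+ optional qval)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"gene_id", "log2fc", "pval"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: DE table lacks columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"{path}: duplicate gene ids {dups[:5]}")
    finite = df["pval"].dropna()
    if ((finite < 0) | (finite > 1)).any():
        raise ValueError(f"{path}: p-values outside [0, 1]")
    return df


def write_de_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# evidence TSV dialect


def _header_comment(seed: Optional[int], config: Optional[Mapping]) -> str:
    cfg_hash = "-"
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        cfg_hash = hashlib.sha256(blob).hexdigest()[:12]
    return f"# pgenmi v{__version__} seed={'-' if seed is None else seed} config_hash={cfg_hash}\n"


def write_evidence_tsv(
    matrix: EvidenceMatrix,
    pvals: DEPValueVector,
    path: Union[str, Path],
    seed: Optional[int] = None,
    config: Optional[Mapping] = None,
) -> None:
    """Write the model-input dialect: ``GENE  PVAL  <col> ...`` with binary
    entries; deterministic output for identical inputs."""
    if matrix.gene_ids != pvals.gene_ids:
        raise ValueError("matrix and p-values must list the same genes in order")
    with open(path, "w") as fh:
        fh.write(_header_comment(seed, config))
        fh.write("GENE\tPVAL\t" + "\t".join(c.name for c in matrix.columns) + "\n")
        for i, gene in enumerate(matrix.gene_ids):
            bits = "\t".join(str(int(b)) for b in matrix.values[i])
            fh.write(f"{gene}\t{pvals.pvals[i]:.17g}\t{bits}\n")


def read_evidence_tsv(path: Union[str, Path]) -> tuple[EvidenceMatrix, DEPValueVector]:
    path = Path(path)
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty evidence file")
    header = lines[0].rstrip("\n").split("\t")
    if header[:2] != ["GENE", "PVAL"]:
        raise ValueError(f"{path}: evidence file must start with GENE and PVAL columns")
    columns = [EvidenceColumnKey.parse(name) for name in header[2:]]
    genes, pvals, rows = [], [], []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.rstrip("\n").split("\t")
        if len(fields) != len(header):
            raise ValueError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        genes.append(fields[0])
        pvals.append(float(fields[1]))
        bits = fields[2:]
        if any(b not in ("0", "1") for b in bits):
            raise ValueError(f"{path}:{lineno}: evidence entries must be 0 or 1")
        rows.append([int(b) for b in bits])
    matrix = EvidenceMatrix(genes, columns, np.array(rows, dtype=np.uint8).reshape(len(genes), len(columns)))
    return matrix, DEPValueVector(genes, np.array(pvals))


# ---------------------------------------------------------------------------
# results


def fit_result_to_dict(result: FitResult, config: Optional[Mapping] = None) -> dict:
    params = result.params
    if isinstance(params, FwParams):
        p = {
            "variant": "fw",
            "w0": params.w0,
            "alpha": params.alpha,
            "tfs": params.tfs,
            "mark_changes": params.mark_changes,
            "w_tf": params.w_tf.tolist(),
            "w_mark": params.w_mark.tolist(),
        }
    else:
        p = {
            "variant": "pgenmi",
            "w0": params.w0,
            "alpha": params.alpha,
            "w": params.w.tolist(),
        }
    return {
        "params": p,
        "loglik": result.loglik,
        "penalized_obj": result.penalized_obj,
        "llr": result.llr,
        "converged": result.converged,
        "null_params": {"w0": result.null_params[0], "alpha": result.null_params[1]},
        "seed": result.seed,
        "n_iter": result.n_iter,
        "config": dict(config) if config else None,
        "version": __version__,
    }


def write_fit_json(
    result: FitResult, path: Union[str, Path], config: Optional[Mapping] = None
) -> None:
    with open(path, "w") as fh:
        json.dump(fit_result_to_dict(result, config), fh, indent=2)
        fh.write("\n")


def write_gene_scores_tsv(
    path: Union[str, Path],
    gene_ids: Sequence[str],
    columns: Mapping[str, np.ndarray],
    seed: Optional[int] = None,
    config: Optional[Mapping] = None,
) -> None:
    """Per-gene score table (e.g. prior, POR, RPOR columns)."""
    with open(path, "w") as fh:
        fh.write(_header_comment(seed, config))
        names = list(columns)
        fh.write("GENE\t" + "\t".join(names) + "\n")
        for i, gene in enumerate(gene_ids):
            vals = "\t".join(f"{columns[c][i]:.6g}" for c in names)
            fh.write(f"{gene}\t{vals}\n")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Flat run configuration mirrored by CLI flags (flags win)."""

    strategy: str = "DiffMark"
    distance_d: int = 50_000
    reg_lambda: float = 0.1
    lambda_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    seed: int = 0
    mode: str = "down"  # analysis mode; never inferred
    peaks_dir: Optional[str] = None
    annotation: Optional[str] = None
    de_table: Optional[str] = None
    out_dir: Optional[str] = None


def load_config(path: Union[str, Path]) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "lambda_grid" in data:
        data["lambda_grid"] = tuple(float(x) for x in data["lambda_grid"])
    cfg = RunConfig(**data)
    for attr in ("peaks_dir", "annotation", "de_table"):
        val = getattr(cfg, attr)
        if val is not None and not Path(val).exists():
            raise FileNotFoundError(f"{attr} path does not exist: {val}")
    return cfg


def file_checksum(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]
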