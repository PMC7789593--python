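"""Synthetic data generation.

Two generators back the test and evaluation machinery without any external
downloads:

* :func:`simulate_dataset` reads the mixture model generatively — binary
  evidence r_gc ~ Bernoulli(density), prior pi_g from the true parameters,
  Z_g ~ Bernoulli(pi_g), and p_g ~ Beta(alpha, 1) when Z_g = 1 else
  Uniform(0, 1).  Defaults mirror the study conditions: 17,200 genes, 20
  TFs, the 8 histone mark-changes, evidence density 0.05 and alpha = 0.2.
* :func:`simulate_genomic_fixture` lays out a toy single-chromosome genome
  with hand-placed and seeded-random peaks so that every evidence-encoding
  edge case (replicate-inconsistent peak, cross-stage overlap, window
  boundary, direction conflict) occurs at least once, and computes the
  expected evidence matrix for every strategy with a naive all-pairs
  interval scan that is independent of the production builder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .containers import (
    DEPValueVector,
    EvidenceColumnKey,
    EvidenceMatrix,
    HISTONE_MARKS,
    PVALUE_FLOOR,
)
from .evidence import (
    EvidenceConfig,
    GeneAnnotation,
    GenomicInterval,
    PeakSet,
)
from .model import FwParams, PGenMiParams

__all__ = [
    "SimulationSpec",
    "SimulatedDataset",
    "GenomicFixture",
    "build_all_strategies",
    "default_mark_changes",
    "default_spec",
    "simulate_dataset",
    "simulate_genomic_fixture",
]


def default_mark_changes() -> list[str]:
    """The 8 mark-change labels of the DiffMark layout (4 marks x up/down)."""
    return [f"{m}-{d}" for m in HISTONE_MARKS for d in ("up", "down")]


def _split_mark_change(label: str) -> tuple[str, str]:
    if label.endswith("-up"):
        return label[:-3], "up"
    if label.endswith("-down"):
        return label[:-5], "down"
    return label, "present"


@dataclass
class SimulationSpec:
    """Generative settings for one synthetic dataset.

    ``correlated`` in [0, 1) mixes in a per-gene shared latent factor: with
    that probability an evidence bit copies a gene-level master draw instead
    of an independent one, emulating co-localized binding while preserving
    the marginal density.
    """

    n_genes: int = 17_200
    n_tfs: int = 20
    mark_changes: list[str] = field(default_factory=default_mark_changes)
    evidence_density: float = 0.05
    true_params: Optional[Union[PGenMiParams, FwParams]] = None
    seed: int = 0
    correlated: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.evidence_density < 1.0:
            raise ValueError(
                f"evidence_density must be in (0, 1), got {self.evidence_density}"
            )
        if not 0.0 <= self.correlated < 1.0:
            raise ValueError("correlated must be in [0, 1)")
        if self.n_genes < 1 or self.n_tfs < 1 or not self.mark_changes:
            raise ValueError("n_genes, n_tfs and mark_changes must be non-empty")

    @property
    def columns(self) -> list[EvidenceColumnKey]:
        keys = []
        for i in range(self.n_tfs):
            tf = f"TF{i:02d}"
            for label in self.mark_changes:
                mark, direction = _split_mark_change(label)
                keys.append(EvidenceColumnKey(tf, mark, direction))
        return keys


@dataclass
class SimulatedDataset:
    """One draw from the generative model, with the latent truth retained."""

    matrix: EvidenceMatrix
    pvals: DEPValueVector
    true_z: np.ndarray
    spec: SimulationSpec


def default_spec(
    seed: int = 0,
    n_genes: int = 17_200,
    n_tfs: int = 20,
    alpha: float = 0.2,
    w0: float = -2.0,
    weight_range: tuple[float, float] = (-3.0, 3.0),
    evidence_density: float = 0.05,
    correlated: float = 0.0,
) -> SimulationSpec:
    """Study-condition defaults with true column weights ~ U(weight_range)."""
    mark_changes = default_mark_changes()
    n_cols = n_tfs * len(mark_changes)
    rng = np.random.default_rng(seed)
    w = rng.uniform(weight_range[0], weight_range[1], size=n_cols)
    params = PGenMiParams(w0=w0, w=w, alpha=alpha)
    return SimulationSpec(
        n_genes=n_genes,
        n_tfs=n_tfs,
        mark_changes=mark_changes,
        evidence_density=evidence_density,
        true_params=params,
        seed=seed,
        correlated=correlated,
    )


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Draw one dataset from the generative model; fully seed-deterministic."""
    rng = np.random.default_rng(spec.seed)
    columns = spec.columns
    n, k = spec.n_genes, len(columns)
    if spec.correlated > 0:
        master = rng.random(n) < spec.evidence_density
        indep = rng.random((n, k)) < spec.evidence_density
        use_master = rng.random((n, k)) < spec.correlated
        X = np.where(use_master, master[:, None], indep).astype(np.uint8)
    else:
        X = (rng.random((n, k)) < spec.evidence_density).astype(np.uint8)

    params = spec.true_params
    if params is None:
        params = PGenMiParams(w0=-2.0, w=np.zeros(k), alpha=0.2)
    w = params.column_weights(columns)
    if w.shape[0] != k:
        raise ValueError(
            f"true parameters cover {w.shape[0]} columns but the layout has {k}"
        )
    logit = params.w0 + X.astype(float) @ w
    pi = 1.0 / (1.0 + np.exp(-np.clip(logit, -700, 700)))
    z = rng.random(n) < pi
    p = np.where(z, rng.beta(params.alpha, 1.0, size=n), rng.random(n))
    p = np.clip(p, PVALUE_FLOOR, 1.0)

    gene_ids = [f"G{i:05d}" for i in range(n)]
    matrix = EvidenceMatrix(gene_ids, columns, X)
    pvals = DEPValueVector(gene_ids, p)
    return SimulatedDataset(matrix=matrix, pvals=pvals, true_z=z.astype(np.uint8), spec=spec)


# ---------------------------------------------------------------------------
# genomic toy fixture with an independent brute-force oracle


def build_all_strategies(fx: "GenomicFixture") -> dict[str, EvidenceMatrix]:
    """Run the production evidence builders on a fixture's peak sets for all
    six strategies (the counterpart of the fixture's brute-force
    ``expected`` matrices)."""
    from .evidence import (
        build_diffacc,
        build_diffmark,
        build_diffmarkaggr,
        build_presacc,
        build_presmark,
        build_tfbs_only,
        call_dynamic_marks,
    )

    dyn = []
    for mark, stages in fx.mark_peaks.items():
        up, down = call_dynamic_marks(
            stages["early"][0], stages["early"][1],
            stages["late"][0], stages["late"][1],
        )
        dyn += [up, down]
    diffmark = build_diffmark(fx.tf_peaks, dyn, fx.genes, fx.config)
    presmark_in = {
        m: [ps for st in ("early", "late") for ps in fx.mark_peaks[m][st]]
        for m in fx.mark_peaks
    }
    return {
        "DiffMark": diffmark,
        "DiffMarkAggr": build_diffmarkaggr(diffmark),
        "PresMark": build_presmark(fx.tf_peaks, presmark_in, fx.genes, fx.config),
        "DiffAcc": build_diffacc(fx.tf_peaks, fx.atac, fx.genes, fx.config),
        "PresAcc": build_presacc(fx.tf_peaks, fx.atac, fx.genes, fx.config),
        "TFBSonly": build_tfbs_only(fx.tf_peaks, fx.genes, fx.config),
    }


@dataclass
class GenomicFixture:
    """Toy peak/annotation data plus brute-force expected evidence matrices."""

    genes: list[GeneAnnotation]
    tf_peaks: dict[str, PeakSet]
    mark_peaks: dict[str, dict[str, list[PeakSet]]]  # mark -> stage -> [rep1, rep2]
    atac: dict[str, PeakSet]  # stage -> peaks
    config: EvidenceConfig
    expected: dict[str, EvidenceMatrix]
    paths: dict[str, str] = field(default_factory=dict)


def _bf_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def _bf_window_overlap(iv: GenomicInterval, chrom: str, w0: int, w1: int) -> bool:
    return iv.chrom == chrom and iv.start < w1 and w0 < iv.end


def _bf_dynamic(early: Sequence[list[GenomicInterval]],
                late: Sequence[list[GenomicInterval]]) -> tuple[list, list]:
    """Naive dynamic-site calls: (up, down). ``early``/``late`` are lists of
    replicate interval lists (one list = single-replicate mode)."""

    def consistent(reps):
        if len(reps) == 1:
            return list(reps[0])
        return [iv for iv in reps[0] if any(_bf_overlap(iv, o) for o in reps[1])]

    early_cons, late_cons = consistent(early), consistent(late)
    early_all = [iv for reps in early for iv in reps]
    late_all = [iv for reps in late for iv in reps]
    down = [iv for iv in early_cons if not any(_bf_overlap(iv, o) for o in late_all)]
    up = [iv for iv in late_cons if not any(_bf_overlap(iv, o) for o in early_all)]
    return up, down


def _bf_directional_bits(
    tfbs: list[GenomicInterval],
    dyn: Mapping[str, list[GenomicInterval]],  # direction -> intervals
    gene: GeneAnnotation,
    d: int,
) -> dict[str, int]:
    """Naive DiffMark-style bit for one (gene, TF, mark): overlap scan plus
    the largest-change conflict rule (ties -> 'up')."""
    w0, w1 = max(0, gene.tss - d), gene.tss + d
    hits = {}
    for direction in ("up", "down"):
        hits[direction] = [
            t
            for t in tfbs
            if _bf_window_overlap(t, gene.chrom, w0, w1)
            and any(_bf_overlap(t, m) for m in dyn[direction])
        ]
    bits = {d_: int(bool(h)) for d_, h in hits.items()}
    if bits["up"] and bits["down"]:
        scores = {}
        for direction in ("up", "down"):
            total = 0
            for t in hits[direction]:
                for m in dyn[direction]:
                    if _bf_overlap(t, m):
                        seg0 = max(t.start, m.start, w0)
                        seg1 = min(t.end, m.end, w1)
                        total += max(0, seg1 - seg0)
            scores[direction] = total
        keep = "up" if scores["up"] >= scores["down"] else "down"
        bits = {d_: int(d_ == keep) for d_ in ("up", "down")}
    return bits


def _bf_expected(
    genes: list[GeneAnnotation],
    tf_peaks: dict[str, PeakSet],
    mark_peaks: dict[str, dict[str, list[PeakSet]]],
    atac: dict[str, PeakSet],
    cfg: EvidenceConfig,
) -> dict[str, EvidenceMatrix]:
    """All six expected matrices by exhaustive all-pairs scanning."""
    tfs = sorted(tf_peaks)
    marks = [m for m in HISTONE_MARKS if m in mark_peaks]
    gene_ids = [g.gene_id for g in genes]
    d = cfg.distance_d

    dyn: dict[str, dict[str, list[GenomicInterval]]] = {}
    for mark in marks:
        up, down = _bf_dynamic(
            [ps.intervals for ps in mark_peaks[mark]["early"]],
            [ps.intervals for ps in mark_peaks[mark]["late"]],
        )
        dyn[mark] = {"up": up, "down": down}
    atac_up, atac_down = _bf_dynamic(
        [atac["early"].intervals], [atac["late"].intervals]
    )

    # DiffMark
    cols_dm = [
        EvidenceColumnKey(tf, mark, direction)
        for tf in tfs for mark in marks for direction in ("up", "down")
    ]
    vals_dm = np.zeros((len(genes), len(cols_dm)), dtype=np.uint8)
    for gi, gene in enumerate(genes):
        j = 0
        for tf in tfs:
            for mark in marks:
                bits = _bf_directional_bits(tf_peaks[tf].intervals, dyn[mark], gene, d)
                vals_dm[gi, j] = bits["up"]
                vals_dm[gi, j + 1] = bits["down"]
                j += 2
    diffmark = EvidenceMatrix(gene_ids, cols_dm, vals_dm)

    # DiffMarkAggr: per-direction OR over marks
    cols_ag = [
        EvidenceColumnKey(tf, "ANY", direction)
        for tf in tfs for direction in ("up", "down")
    ]
    vals_ag = np.zeros((len(genes), len(cols_ag)), dtype=np.uint8)
    for j, key in enumerate(cols_ag):
        src = [
            i for i, c in enumerate(cols_dm)
            if c.tf == key.tf and c.direction == key.direction
        ]
        vals_ag[:, j] = vals_dm[:, src].max(axis=1)
    aggr = EvidenceMatrix(gene_ids, cols_ag, vals_ag)

    # PresMark
    cols_pm = [EvidenceColumnKey(tf, mark, "present") for tf in tfs for mark in marks]
    vals_pm = np.zeros((len(genes), len(cols_pm)), dtype=np.uint8)
    for gi, gene in enumerate(genes):
        w0, w1 = max(0, gene.tss - d), gene.tss + d
        for j, key in enumerate(cols_pm):
            any_stage = [
                iv
                for stage in ("early", "late")
                for ps in mark_peaks[key.mark][stage]
                for iv in ps.intervals
            ]
            hit = any(
                _bf_window_overlap(t, gene.chrom, w0, w1)
                and any(_bf_overlap(t, m) for m in any_stage)
                for t in tf_peaks[key.tf].intervals
            )
            vals_pm[gi, j] = int(hit)
    presmark = EvidenceMatrix(gene_ids, cols_pm, vals_pm)

    # DiffAcc
    cols_da = [
        EvidenceColumnKey(tf, "ATAC", direction)
        for tf in tfs for direction in ("up", "down")
    ]
    vals_da = np.zeros((len(genes), len(cols_da)), dtype=np.uint8)
    for gi, gene in enumerate(genes):
        for ti, tf in enumerate(tfs):
            bits = _bf_directional_bits(
                tf_peaks[tf].intervals, {"up": atac_up, "down": atac_down}, gene, d
            )
            vals_da[gi, 2 * ti] = bits["up"]
            vals_da[gi, 2 * ti + 1] = bits["down"]
    diffacc = EvidenceMatrix(gene_ids, cols_da, vals_da)

    # PresAcc
    cols_pa = [EvidenceColumnKey(tf, "ATAC", "present") for tf in tfs]
    vals_pa = np.zeros((len(genes), len(cols_pa)), dtype=np.uint8)
    atac_all = atac["early"].intervals + atac["late"].intervals
    for gi, gene in enumerate(genes):
        w0, w1 = max(0, gene.tss - d), gene.tss + d
        for j, tf in enumerate(tfs):
            hit = any(
                _bf_window_overlap(t, gene.chrom, w0, w1)
                and any(_bf_overlap(t, a) for a in atac_all)
                for t in tf_peaks[tf].intervals
            )
            vals_pa[gi, j] = int(hit)
    presacc = EvidenceMatrix(gene_ids, cols_pa, vals_pa)

    # TFBS-only
    cols_to = [EvidenceColumnKey(tf, "TFBS", "present") for tf in tfs]
    vals_to = np.zeros((len(genes), len(cols_to)), dtype=np.uint8)
    for gi, gene in enumerate(genes):
        w0, w1 = max(0, gene.tss - d), gene.tss + d
        for j, tf in enumerate(tfs):
            vals_to[gi, j] = int(
                any(
                    _bf_window_overlap(t, gene.chrom, w0, w1)
                    for t in tf_peaks[tf].intervals
                )
            )
    tfbsonly = EvidenceMatrix(gene_ids, cols_to, vals_to)

    return {
        "DiffMark": diffmark,
        "DiffMarkAggr": aggr,
        "PresMark": presmark,
        "DiffAcc": diffacc,
        "PresAcc": presacc,
        "TFBSonly": tfbsonly,
    }


def simulate_genomic_fixture(
    n_genes: int = 12,
    n_tfs: int = 3,
    seed: int = 0,
    out_dir: Optional[Union[str, Path]] = None,
    distance_d: int = 1000,
) -> GenomicFixture:
    """Build a toy single-chromosome dataset exercising every evidence
    pattern, with expected matrices from the brute-force oracle.

    Genes sit every 10 kb on chromosome ``chrS`` (synthetic); the window
    half-width is 1 kb so windows never overlap.  Genes 0 and 1 carry
    hand-placed peaks covering the edge cases (replicate-inconsistent peak,
    1-bp cross-stage overlap, half-open window boundary, direction
    conflict); the remaining genes receive seeded random peaks.
    """
    if n_genes < 4 or n_genes > 100:
        raise ValueError("fixture supports 4..100 genes")
    if n_tfs < 1:
        raise ValueError("need at least one TF")
    rng = np.random.default_rng(seed)
    chrom = "chrS"
    spacing, d = 10_000, distance_d

    genes = []
    for i in range(n_genes):
        start = spacing * i + 5_000
        strand = "+" if i % 2 == 0 else "-"
        body = (start, start + 2_000)
        tss = body[0] if strand == "+" else body[1]
        # shift bodies so the TSS lands at spacing*i + 5000 on either strand
        if strand == "-":
            body = (start - 2_000, start)
        genes.append(
            GeneAnnotation(
                gene_id=f"G{i:03d}", chrom=chrom, strand=strand, tss=start,
                body_start=body[0], body_end=body[1],
            )
        )

    tfs = [f"TF{i:02d}" for i in range(n_tfs)]
    tf_ivs: dict[str, list[GenomicInterval]] = {tf: [] for tf in tfs}
    mark_ivs: dict[str, dict[str, dict[int, list[GenomicInterval]]]] = {
        m: {"early": {0: [], 1: []}, "late": {0: [], 1: []}} for m in HISTONE_MARKS
    }
    atac_ivs: dict[str, list[GenomicInterval]] = {"early": [], "late": []}

    def iv(start: int, end: int) -> GenomicInterval:
        return GenomicInterval(chrom=chrom, start=start, end=end)

    # ---- hand-placed patterns around gene 0 (tss 5000, window [4000, 6000))
    t0 = tfs[0]
    tf_ivs[t0].append(iv(4500, 4700))  # TFBS A
    for rep in (0, 1):  # consistent early peak, no late overlap -> 'down'
        mark_ivs["H3K27ac"]["early"][rep].append(iv(4550, 4650))
    mark_ivs["H3K27ac"]["early"][0].append(iv(4800, 4900))  # rep1-only: nowhere
    for rep in (0, 1):  # early-consistent peak killed by 1-bp late overlap
        mark_ivs["H3K27ac"]["early"][rep].append(iv(5200, 5300))
    mark_ivs["H3K27ac"]["late"][0].append(iv(5299, 5400))

    # ---- hand-placed patterns around gene 1 (tss 15000, window [14000, 16000))
    tf_ivs[t0].append(iv(15999, 16100))  # last-base-in-window TFBS B
    tf_ivs[t0].append(iv(16000, 16100))  # first-base-outside TFBS C
    for rep in (0, 1):  # late-exclusive mark over B and C -> 'up' via B only
        mark_ivs["H3K27ac"]["late"][rep].append(iv(15990, 16150))
    # direction conflict on H3K4me1: down overlap 200 bp beats up overlap 100 bp
    tf_ivs[t0].append(iv(14500, 14800))  # TFBS D
    for rep in (0, 1):
        mark_ivs["H3K4me1"]["late"][rep].append(iv(14500, 14600))   # up, 100 bp
        mark_ivs["H3K4me1"]["early"][rep].append(iv(14600, 14850))  # down, 200 bp
    # ATAC: early-exclusive peak over TFBS D -> DiffAcc 'down' for gene 1
    atac_ivs["early"].append(iv(14700, 14900))
    atac_ivs["late"].append(iv(15100, 15200))  # late-exclusive, no TFBS overlap

    # ---- seeded random peaks around the remaining genes
    for gi in range(2, n_genes):
        tss = genes[gi].tss
        for tf in tfs:
            if rng.random() < 0.6:
                offset = int(rng.integers(-1400, 1200))
                start = max(0, tss + offset)
                tf_ivs[tf].append(iv(start, start + 200))
        for mark in HISTONE_MARKS:
            for stage in ("early", "late"):
                if rng.random() < 0.5:
                    offset = int(rng.integers(-1400, 1100))
                    start = max(0, tss + offset)
                    base = iv(start, start + 300)
                    mark_ivs[mark][stage][0].append(base)
                    if rng.random() < 0.8:  # replicate-consistent most times
                        jitter = int(rng.integers(-50, 50))
                        mark_ivs[mark][stage][1].append(
                            iv(max(0, start + jitter), start + 300 + jitter)
                        )
        for stage in ("early", "late"):
            if rng.random() < 0.5:
                offset = int(rng.integers(-1400, 1100))
                start = max(0, tss + offset)
                atac_ivs[stage].append(iv(start, start + 250))

    tf_peaks = {tf: PeakSet(label=tf, intervals=ivs) for tf, ivs in tf_ivs.items()}
    mark_peaks = {
        mark: {
            stage: [
                PeakSet(label=mark, intervals=mark_ivs[mark][stage][rep],
                        stage=stage, replicate=f"rep{rep + 1}")
                for rep in (0, 1)
            ]
            for stage in ("early", "late")
        }
        for mark in HISTONE_MARKS
    }
    atac = {
        stage: PeakSet(label="ATAC", intervals=atac_ivs[stage], stage=stage)
        for stage in ("early", "late")
    }
    cfg = EvidenceConfig(strategy="DiffMark", distance_d=d)
    expected = _bf_expected(genes, tf_peaks, mark_peaks, atac, cfg)

    paths: dict[str, str] = {}
    if out_dir is not None:
        from . import io as pio  # deferred: io imports this module's siblings

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        annot = out / "genes.tsv"
        pio.write_gene_annotation(genes, annot)
        paths["annotation"] = str(annot)
        for tf, ps in tf_peaks.items():
            p = out / f"tf_{tf}.narrowPeak"
            pio.write_narrowpeak(ps, p)
            paths[f"tf:{tf}"] = str(p)
        for mark, stages in mark_peaks.items():
            for stage, reps in stages.items():
                for ri, ps in enumerate(reps, start=1):
                    p = out / f"mark_{mark}_{stage}_rep{ri}.narrowPeak"
                    pio.write_narrowpeak(ps, p)
                    paths[f"mark:{mark}:{stage}:rep{ri}"] = str(p)
        for stage, ps in atac.items():
            p = out / f"atac_{stage}.narrowPeak"
            pio.write_narrowpeak(ps, p)
            paths[f"atac:{stage}"] = str(p)

    return GenomicFixture(
        genes=genes, tf_peaks=tf_peaks, mark_peaks=mark_peaks, atac=atac,
        config=cfg, expected=expected, paths=paths,
    )
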