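"""Model evaluation: cross-validation, permutation nulls, TF-profile
specificity analyses, regulon enrichment and gene signatures.

Cross-validation operates on the gene axis: genes are partitioned into
train/(validation/)test sets, the model is trained on the training genes and
scored as a held-out LLR — the fitted model's log-likelihood on test genes
minus that of the evidence-free null fitted to the same training genes.
Two schemes are supported: an 80/20 split for hyperparameter selection
(window distance d and L2 coefficient lambda) and a 72/18/10 split where the
validation set picks (d, lambda) per repeat and test LLRs compare evidence
strategies head-to-head.

The permutation null reassigns each evidence column independently among
genes and refits the model, giving an empirical LLR distribution against
which the observed LLR is expressed as a z-score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import DEPValueVector, EvidenceMatrix
from .model import NullMixture, PGenMi, TrainingConfig

__all__ = [
    "SplitScheme",
    "CVResult",
    "NullDistribution",
    "TopRankResult",
    "cross_validate",
    "paired_strategy_wins",
    "shuffled_null",
    "shuffle_evidence",
    "tf_feature_vectors",
    "jaccard_similarity",
    "select_distinct_tfs",
    "top_rank_frequency",
    "hypergeometric_enrichment",
    "gene_signature",
]


@dataclass
class SplitScheme:
    """Gene partition fractions (train, validation, test) and repeat count.

    Validation may be 0 (hyperparameter mode).  The same (seed, repeat)
    always produces the same partition, so runs with different evidence
    matrices over the same genes are paired.
    """

    fractions: tuple[float, float, float] = (0.72, 0.18, 0.10)
    n_repeats: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        tr, va, te = self.fractions
        if tr <= 0 or te < 0 or va < 0 or abs(tr + va + te - 1.0) > 1e-9:
            raise ValueError(f"fractions must be >= 0, train > 0, and sum to 1, got {self.fractions}")

    def partition(self, n_genes: int, repeat: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Disjoint (train, validation, test) index arrays covering all genes."""
        rng = np.random.default_rng([self.seed, repeat])
        perm = rng.permutation(n_genes)
        n_tr = int(round(self.fractions[0] * n_genes))
        n_va = int(round(self.fractions[1] * n_genes))
        return perm[:n_tr], perm[n_tr : n_tr + n_va], perm[n_tr + n_va :]


@dataclass
class CVResult:
    """Per-repeat held-out LLRs plus the chosen hyperparameters.

    ``records`` has one row per (repeat, d, lambda) in hyperparameter mode,
    or one row per repeat (at the validation-chosen (d, lambda)) in
    strategy-comparison mode.  ``summary`` is the mean over repeats of the
    summed up+down test LLR; ``best_d``/``best_lambda`` maximize it.
    """

    records: pd.DataFrame
    summary: float
    best_d: int
    best_lambda: float
    mode: str  # {"hyperparameter", "strategy"}


def _held_out_llr(
    train_mat: EvidenceMatrix,
    train_p: DEPValueVector,
    eval_mat: EvidenceMatrix,
    eval_p: DEPValueVector,
    reg_lambda: float,
    cfg: TrainingConfig,
) -> tuple[PGenMi, NullMixture, float]:
    model = PGenMi(
        reg_lambda=reg_lambda, restarts=cfg.restarts,
        max_iter=cfg.max_iter, tol=cfg.tol, random_state=cfg.seed,
    ).fit(train_mat, train_p)
    return model, model.null_, model.llr_on(eval_mat, eval_p, model.null_)


def cross_validate(
    matrices_by_d: Mapping[int, EvidenceMatrix],
    pvals_up: DEPValueVector,
    pvals_down: Optional[DEPValueVector],
    scheme: SplitScheme,
    lambda_grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0),
    cfg: Optional[TrainingConfig] = None,
) -> CVResult:
    """Repeated random-split cross-validation over (d, lambda).

    With a zero validation fraction (e.g. 80/20) every (d, lambda) pair is
    scored on the test genes of every repeat and the best pair maximizes the
    mean summed up+down test LLR.  With a positive validation fraction
    (e.g. 72/18/10) the validation set picks (d, lambda) within each repeat
    and only the chosen pair's test LLR is recorded.
    """
    cfg = cfg or TrainingConfig(restarts=2)
    gene_ids = None
    for d, mat in matrices_by_d.items():
        if gene_ids is None:
            gene_ids = mat.gene_ids
        elif mat.gene_ids != gene_ids:
            raise ValueError(f"evidence matrix for d={d} lists different genes")
    analyses = [("up", pvals_up)]
    if pvals_down is not None:
        analyses.append(("down", pvals_down))
    for _, pv in analyses:
        if pv.gene_ids != gene_ids:
            raise ValueError("p-value vector genes differ from the matrices")
    n = len(gene_ids)
    has_validation = scheme.fractions[1] > 0
    rows = []
    for r in range(scheme.n_repeats):
        tr, va, te = scheme.partition(n, r)
        scored: dict[tuple[int, float], dict[str, float]] = {}
        for d, mat in matrices_by_d.items():
            mat_tr, mat_va, mat_te = mat.take(tr), mat.take(va), mat.take(te)
            for lam in lambda_grid:
                entry: dict[str, float] = {}
                for mode, pv in analyses:
                    model, null, te_llr = _held_out_llr(
                        mat_tr, pv.take(tr), mat_te, pv.take(te), lam, cfg
                    )
                    entry[f"test_llr_{mode}"] = te_llr
                    if has_validation:
                        entry[f"val_llr_{mode}"] = model.llr_on(
                            mat_va, pv.take(va), null
                        )
                scored[(d, lam)] = entry
        if has_validation:
            # validation picks (d, lambda); only its test LLR is kept
            def val_total(key):
                e = scored[key]
                return sum(v for k, v in e.items() if k.startswith("val_llr"))
            best = max(scored, key=lambda k: (val_total(k), -k[0], -k[1]))
            row = {"repeat": r, "d": best[0], "lambda": best[1]}
            row.update({k: v for k, v in scored[best].items() if k.startswith("test")})
            rows.append(row)
        else:
            for (d, lam), entry in scored.items():
                row = {"repeat": r, "d": d, "lambda": lam}
                row.update(entry)
                rows.append(row)
    records = pd.DataFrame(rows)
    test_cols = [c for c in records.columns if c.startswith("test_llr")]
    records["test_llr_total"] = records[test_cols].sum(axis=1)
    if has_validation:
        summary = float(records["test_llr_total"].mean())
        best_d = int(records["d"].mode().iloc[0])
        best_lambda = float(records["lambda"].mode().iloc[0])
        mode = "strategy"
    else:
        by_pair = records.groupby(["d", "lambda"])["test_llr_total"].mean()
        best_d, best_lambda = max(
            by_pair.index, key=lambda k: (by_pair[k], -k[0], -k[1])
        )
        summary = float(by_pair[(best_d, best_lambda)])
        best_d, best_lambda = int(best_d), float(best_lambda)
        mode = "hyperparameter"
    return CVResult(records=records, summary=summary, best_d=best_d,
                    best_lambda=best_lambda, mode=mode)


def paired_strategy_wins(cv_a: CVResult, cv_b: CVResult) -> tuple[int, int, int]:
    """Per-repeat paired comparison of two strategies run with the same
    SplitScheme: (wins_a, wins_b, ties) on summed test LLR, strict
    inequality — exact ties count for neither."""
    a = cv_a.records.groupby("repeat")["test_llr_total"].max()
    b = cv_b.records.groupby("repeat")["test_llr_total"].max()
    if not a.index.equals(b.index):
        raise ValueError("CV results cover different repeats")
    wins_a = int((a > b).sum())
    wins_b = int((b > a).sum())
    return wins_a, wins_b, len(a) - wins_a - wins_b


# ---------------------------------------------------------------------------
# permutation null


@dataclass
class NullDistribution:
    """Empirical LLR distribution from column-shuffled evidence."""

    llrs: np.ndarray
    mean: float
    sd: float

    def z_score(self, observed_llr: float) -> float:
        return (observed_llr - self.mean) / self.sd


def shuffle_evidence(matrix: EvidenceMatrix, rng: np.random.Generator) -> EvidenceMatrix:
    """Independently permute each evidence column's bits among genes;
    column marginals (counts of 1s) are preserved exactly."""
    values = np.empty_like(matrix.values)
    for j in range(matrix.n_columns):
        values[:, j] = matrix.values[rng.permutation(matrix.n_genes), j]
    return EvidenceMatrix(list(matrix.gene_ids), list(matrix.columns), values)


def shuffled_null(
    matrix: EvidenceMatrix,
    pvals: DEPValueVector,
    cfg: Optional[TrainingConfig] = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> NullDistribution:
    """Train on column-shuffled evidence ``n_perm`` times; returns the
    resulting LLR distribution.  (d, lambda) stay fixed at the values used
    for the observed fit."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cfg = cfg or TrainingConfig(restarts=1)
    rng = np.random.default_rng(seed)
    llrs = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = shuffle_evidence(matrix, rng)
        model = PGenMi(
            reg_lambda=cfg.reg_lambda, restarts=cfg.restarts,
            max_iter=cfg.max_iter, tol=cfg.tol, random_state=cfg.seed,
        ).fit(shuffled, pvals)
        llrs[i] = model.llr_
    return NullDistribution(llrs=llrs, mean=float(llrs.mean()), sd=float(llrs.std(ddof=1)) if n_perm > 1 else float("nan"))


# ---------------------------------------------------------------------------
# TF-profile similarity


def tf_feature_vectors(matrix: EvidenceMatrix) -> dict[str, np.ndarray]:
    """Per-TF gene-length feature vector: disjunction of all of that TF's
    evidence columns."""
    out = {}
    for tf in matrix.tfs:
        idx = matrix.column_indices_for_tf(tf)
        out[tf] = matrix.values[:, idx].max(axis=1)
    return out


def jaccard_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """|u AND v| / |u OR v| for binary vectors; 0 when both are all-zero."""
    u = np.asarray(u, dtype=bool)
    v = np.asarray(v, dtype=bool)
    if u.shape != v.shape:
        raise ValueError(f"vector lengths differ: {u.shape} vs {v.shape}")
    union = np.count_nonzero(u | v)
    if union == 0:
        return 0.0
    return np.count_nonzero(u & v) / union


def select_distinct_tfs(
    foreign_matrix: EvidenceMatrix,
    reference_matrix: EvidenceMatrix,
    cutoff: float = 0.2,
) -> list[str]:
    """Foreign-cell-line TF profiles dissimilar to every reference profile.

    Each foreign TF's score is its maximum Jaccard similarity against any
    reference TF feature vector; TFs scoring below ``cutoff`` are returned
    (sorted by name).
    """
    foreign = tf_feature_vectors(foreign_matrix)
    reference = tf_feature_vectors(reference_matrix)
    selected = []
    for tf, vec in foreign.items():
        score = max(
            (jaccard_similarity(vec, ref) for ref in reference.values()),
            default=0.0,
        )
        if score < cutoff:
            selected.append(tf)
    return sorted(selected)


# ---------------------------------------------------------------------------
# per-TF top-rank frequency


@dataclass
class TopRankResult:
    frequency: float
    mean_llr: float
    llrs: np.ndarray
    top_counts: int


def top_rank_frequency(
    target_matrix: EvidenceMatrix,
    distractor_matrix: EvidenceMatrix,
    pvals: DEPValueVector,
    cfg: Optional[TrainingConfig] = None,
    n_iter: int = 100,
    pool_size: int = 19,
    seed: int = 0,
) -> TopRankResult:
    """How often the target TF ranks first by ΔLLR among itself plus
    ``pool_size`` distractor TF profiles sampled per iteration.

    ``target_matrix`` holds only the target TF's evidence columns;
    ``distractor_matrix`` holds the distractor pool (same gene universe).
    Also reports the mean full-data LLR over iterations.
    """
    cfg = cfg or TrainingConfig(restarts=1)
    if target_matrix.gene_ids != distractor_matrix.gene_ids:
        raise ValueError("target and distractor matrices must share genes")
    target_tfs = target_matrix.tfs
    if len(target_tfs) != 1:
        raise ValueError("target matrix must contain exactly one TF")
    target_tf = target_tfs[0]
    pool_tfs = distractor_matrix.tfs
    if pool_size > len(pool_tfs):
        raise ValueError("pool_size exceeds the distractor pool")
    rng = np.random.default_rng(seed)
    llrs = np.empty(n_iter)
    top = 0
    for i in range(n_iter):
        chosen = rng.choice(pool_tfs, size=pool_size, replace=False)
        cols = [
            j
            for tf in chosen
            for j in distractor_matrix.column_indices_for_tf(tf)
        ]
        combined = target_matrix.hstack(distractor_matrix.select_columns(cols))
        model = PGenMi(
            reg_lambda=cfg.reg_lambda, restarts=cfg.restarts,
            max_iter=cfg.max_iter, tol=cfg.tol, random_state=cfg.seed,
        ).fit(combined, pvals)
        llrs[i] = model.llr_
        ranking = model.rank_tfs(combined, pvals)
        if ranking[0][0] == target_tf:
            top += 1
    return TopRankResult(
        frequency=top / n_iter, mean_llr=float(llrs.mean()), llrs=llrs,
        top_counts=top,
    )


# ---------------------------------------------------------------------------
# enrichment and signatures


def hypergeometric_enrichment(
    set_a_size: int,
    set_b_size: int,
    overlap: int,
    universe: int,
    inclusive: bool = True,
) -> float:
    """Exact upper-tail enrichment p-value for the intersection of two gene
    sets drawn from a common universe.

    With ``inclusive=True`` (default) this is P(X >= overlap); with
    ``inclusive=False`` it is the strictly-greater tail P(X > overlap),
    the convention some enrichment reports use (a raw survival-function
    call)."""
    if not 0 <= overlap <= min(set_a_size, set_b_size) <= max(set_a_size, set_b_size) <= universe:
        raise ValueError(
            "require 0 <= overlap <= min(set sizes) <= universe, got "
            f"overlap={overlap}, sizes=({set_a_size}, {set_b_size}), "
            f"universe={universe}"
        )
    k = overlap - 1 if inclusive else overlap
    return float(hypergeom.sf(k, universe, set_b_size, set_a_size))


def gene_signature(
    rpor_tables: Mapping[str, Mapping[str, float]],
    tfs: Sequence[str],
    n: int = 70,
) -> list[str]:
    """Top-n genes by the product of RPOR scores over the listed TFs.

    ``rpor_tables[tf]`` maps gene id -> RPOR under that TF.  Genes must be
    shared across the listed TFs' tables; ties in the product are broken by
    gene id.
    """
    if not tfs:
        raise ValueError("at least one TF is required")
    missing = [tf for tf in tfs if tf not in rpor_tables]
    if missing:
        raise KeyError(f"no RPOR table for TFs: {missing}")
    frames = {tf: pd.Series(dict(rpor_tables[tf]), dtype=float) for tf in tfs}
    table = pd.DataFrame(frames).dropna()
    score = table.prod(axis=1)
    ranked = score.sort_index().sort_values(ascending=False, kind="stable")
    return ranked.index[:n].tolist()
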