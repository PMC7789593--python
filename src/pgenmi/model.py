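"""Beta-uniform mixture models of DE p-values with evidence-driven priors.

The generative story: each gene g carries a hidden indicator Z_g of whether
its differential expression is mediated by any of the profiled TFs.  The
prior Pr(Z_g = 1) is a logistic function of the gene's binary cis-regulatory
evidence r_g (weighted sum plus intercept); the observed DE p-value is
Uniform(0,1) given Z_g = 0 and Beta(alpha, 1) — a density alpha * p^(alpha-1)
skewed toward small p for alpha < 1 — given Z_g = 1.  Z is never sampled
during inference; the likelihood marginalizes it analytically.

Three estimators are provided, all scikit-learn compatible:

* :class:`PGenMi` — one free weight per evidence column (w_tm),
* :class:`FwPGenMi` — factorized weights, w_tm = w_t * w_m, so each TF and
  each mark-change has a single signed role (activator/repressor),
* :class:`NullMixture` — the evidence-free null (intercept + alpha only).

Training maximizes the L2-regularized log-likelihood with L-BFGS-B on
analytic gradients; the penalty covers the evidence weights only, never the
intercept or alpha.  Model quality is summarized as LLR: the unpenalized
log-likelihood of the fitted model minus that of the null fitted to the
same genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .containers import (
    DEPValueVector,
    EvidenceColumnKey,
    EvidenceMatrix,
    check_aligned,
    clamp_pvalues,
)

__all__ = [
    "PGenMiParams",
    "FwParams",
    "TrainingConfig",
    "FitResult",
    "NullMixture",
    "PGenMi",
    "FwPGenMi",
    "prior_probability",
    "gene_log_density",
    "objective",
    "fit",
    "tf_delta_llr",
    "posterior_odds",
    "rpor",
]

# optimizer bound on the raw (pre-sigmoid) alpha parameter; sigmoid(+/-30)
# is within 1e-13 of the open-interval limits, safely inside float precision
_ALPHA_RAW_BOUND = 30.0


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class PGenMiParams:
    """Free-weight parameters: intercept, one weight per evidence column,
    and the Beta shape alpha in (0, 1]."""

    w0: float
    w: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")

    def column_weights(self, columns: Optional[Sequence[EvidenceColumnKey]] = None) -> np.ndarray:
        if columns is not None and len(columns) != self.w.shape[0]:
            raise ValueError(
                f"parameter vector has {self.w.shape[0]} weights but the "
                f"matrix has {len(columns)} columns"
            )
        return self.w


@dataclass
class FwParams:
    """Factorized parameters: per-TF and per-mark-change weights; the implied
    weight of column (t, m) is ``w_tf[t] * w_mark[m]``."""

    w0: float
    tfs: list[str]
    mark_changes: list[str]
    w_tf: np.ndarray
    w_mark: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        self.w_tf = np.asarray(self.w_tf, dtype=float)
        self.w_mark = np.asarray(self.w_mark, dtype=float)
        if self.w_tf.shape[0] != len(self.tfs):
            raise ValueError("w_tf length must match the TF list")
        if self.w_mark.shape[0] != len(self.mark_changes):
            raise ValueError("w_mark length must match the mark-change list")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")

    def column_weights(self, columns: Sequence[EvidenceColumnKey]) -> np.ndarray:
        tf_pos = {t: i for i, t in enumerate(self.tfs)}
        mk_pos = {m: i for i, m in enumerate(self.mark_changes)}
        try:
            ti = np.array([tf_pos[c.tf] for c in columns])
            mi = np.array([mk_pos[c.mark_change] for c in columns])
        except KeyError as exc:
            raise ValueError(f"column key {exc} not covered by the factorized "
                             "parameterization") from exc
        return self.w_tf[ti] * self.w_mark[mi]


@dataclass
class TrainingConfig:
    """Optimizer controls shared by every variant."""

    reg_lambda: float = 0.1
    seed: int = 0
    restarts: int = 5
    max_iter: int = 500
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.reg_lambda < 0:
            raise ValueError("reg_lambda must be >= 0")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class FitResult:
    """Outcome of one training run.

    ``loglik`` is the UNPENALIZED log-likelihood at the optimum;
    ``penalized_obj`` is the regularized objective actually maximized;
    ``llr`` compares ``loglik`` with a null fit on the same genes.
    """

    params: Union[PGenMiParams, FwParams]
    loglik: float
    penalized_obj: float
    llr: float
    converged: bool
    null_params: tuple[float, float]  # (w0, alpha) of the paired null fit
    seed: int = 0
    n_iter: int = 0
    restart_objectives: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# stable primitives


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log_mixture_density(logit: np.ndarray, alpha: float, log_p: np.ndarray) -> np.ndarray:
    """log[(1-pi) + pi * alpha * p^(alpha-1)] via log-sum-exp; pi=sigmoid(logit)."""
    log_pi = -np.logaddexp(0.0, -logit)
    log_1mpi = -np.logaddexp(0.0, logit)
    log_beta = np.log(alpha) + (alpha - 1.0) * log_p
    return np.logaddexp(log_1mpi, log_pi + log_beta)


def _as_arrays(
    matrix: Union[EvidenceMatrix, np.ndarray, None],
    pvals: Union[DEPValueVector, np.ndarray],
) -> tuple[Optional[np.ndarray], np.ndarray]:
    if isinstance(matrix, EvidenceMatrix) and isinstance(pvals, DEPValueVector):
        check_aligned(matrix, pvals)
    X = None
    if matrix is not None:
        X = matrix.values if isinstance(matrix, EvidenceMatrix) else np.asarray(matrix)
        X = X.astype(float)
    p = pvals.pvals if isinstance(pvals, DEPValueVector) else clamp_pvalues(pvals)
    if X is not None and X.shape[0] != p.shape[0]:
        raise ValueError(
            f"evidence matrix has {X.shape[0]} rows but {p.shape[0]} p-values"
        )
    return X, p


# ---------------------------------------------------------------------------
# spec-level functional surface


def prior_probability(
    params: Union[PGenMiParams, FwParams],
    evidence_row: np.ndarray,
    columns: Optional[Sequence[EvidenceColumnKey]] = None,
) -> float:
    """Pr(Z_g = 1): logistic of the intercept plus the weighted evidence sum.

    For factorized parameters ``columns`` must be given so each evidence
    entry can be matched to its (TF, mark-change) weight product.
    """
    row = np.asarray(evidence_row, dtype=float)
    if isinstance(params, FwParams):
        if columns is None:
            raise ValueError("factorized parameters require the column keys")
        w = params.column_weights(columns)
    else:
        w = params.column_weights(columns)
    if row.shape[0] != w.shape[0]:
        raise ValueError(
            f"evidence row has {row.shape[0]} entries but the weight layout "
            f"expects {w.shape[0]}"
        )
    logit = params.w0 + float(row @ w)
    return float(_sigmoid(np.array([logit]))[0])


def gene_log_density(
    params: Union[PGenMiParams, FwParams],
    pval: float,
    evidence_row: np.ndarray,
    columns: Optional[Sequence[EvidenceColumnKey]] = None,
) -> float:
    """Log marginal density of one gene's p-value, Z summed out."""
    if not 0.0 < pval <= 1.0:
        raise ValueError(f"p-value must be in (0, 1], got {pval}")
    if not 0.0 < params.alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {params.alpha}")
    row = np.asarray(evidence_row, dtype=float)
    if isinstance(params, FwParams) and columns is None:
        raise ValueError("factorized parameters require the column keys")
    w = params.column_weights(columns)
    if row.shape[0] != w.shape[0]:
        raise ValueError(
            f"evidence row has {row.shape[0]} entries but the weight layout "
            f"expects {w.shape[0]}"
        )
    logit = params.w0 + float(row @ w)
    return float(
        _log_mixture_density(np.array([logit]), params.alpha, np.log(np.array([pval])))[0]
    )


def objective(
    params: Union[PGenMiParams, FwParams],
    matrix: EvidenceMatrix,
    pvals: DEPValueVector,
    cfg: TrainingConfig,
) -> float:
    """Regularized objective: total log-likelihood minus lambda * sum of
    squared evidence weights (intercept and alpha are unpenalized)."""
    X, p = _as_arrays(matrix, pvals)
    w = params.column_weights(matrix.columns)
    logit = params.w0 + X @ w
    ll = float(_log_mixture_density(logit, params.alpha, np.log(p)).sum())
    if isinstance(params, FwParams):
        penalty = float(np.sum(params.w_tf**2) + np.sum(params.w_mark**2))
    else:
        penalty = float(np.sum(w**2))
    return ll - cfg.reg_lambda * penalty


# ---------------------------------------------------------------------------
# optimizer core (shared by all estimators)


def _pack_neg_objective(X, log_p, lam, ti=None, mi=None, n_tf=0, n_mk=0,
                        fix_mark_weights=False):
    """Return f(theta) -> (neg objective, neg gradient).

    Free-weight layout:   theta = [w0, w_1..k, a_raw]
    Factorized layout:    theta = [w0, w_tf_1..T, w_mk_1..M, a_raw]
    with alpha = sigmoid(a_raw).
    """
    factorized = ti is not None

    def fun(theta: np.ndarray) -> tuple[float, np.ndarray]:
        w0 = theta[0]
        a_raw = theta[-1]
        alpha = float(np.clip(_sigmoid(np.array([a_raw]))[0], 1e-12, 1.0 - 1e-12))
        if factorized:
            w_tf = theta[1 : 1 + n_tf]
            w_mk = np.ones(n_mk) if fix_mark_weights else theta[1 + n_tf : 1 + n_tf + n_mk]
            w = w_tf[ti] * w_mk[mi]
            penalty = np.sum(w_tf**2) + (0.0 if fix_mark_weights else np.sum(w_mk**2))
        else:
            w = theta[1:-1]
            penalty = np.sum(w**2)

        logit = w0 + (X @ w if X is not None else 0.0)
        logit = np.broadcast_to(np.atleast_1d(logit), log_p.shape).astype(float)
        log_f = _log_mixture_density(logit, alpha, log_p)
        obj = log_f.sum() - lam * penalty

        # gradient pieces in linear space; magnitudes bounded by the p-value
        # floor (B <= alpha * floor^(alpha-1) << float64 overflow)
        pi = _sigmoid(logit)
        B = np.exp(np.log(alpha) + (alpha - 1.0) * log_p)
        f = np.exp(log_f)
        s = pi * (1.0 - pi) * (B - 1.0) / f          # d log f / d logit
        dalpha = pi * B * (1.0 / alpha + log_p) / f  # d log f / d alpha

        g = np.empty_like(theta)
        g[0] = s.sum()
        if factorized:
            g_col = X.T @ s if X is not None else np.zeros(len(ti))
            g_tf = np.zeros(n_tf)
            np.add.at(g_tf, ti, g_col * w_mk[mi])
            g[1 : 1 + n_tf] = g_tf - 2.0 * lam * w_tf
            if not fix_mark_weights:
                g_mk = np.zeros(n_mk)
                np.add.at(g_mk, mi, g_col * w_tf[ti])
                g[1 + n_tf : 1 + n_tf + n_mk] = g_mk - 2.0 * lam * w_mk
        elif X is not None:
            g[1:-1] = X.T @ s - 2.0 * lam * w
        g[-1] = dalpha.sum() * alpha * (1.0 - alpha)  # chain through sigmoid
        return -obj, -g

    return fun


def _optimize(fun, theta0_list, max_iter, tol):
    """Best-of-restarts L-BFGS-B; returns (theta, neg_obj, converged, n_iter, objs)."""
    best = None
    objs = []
    bounds = None
    for theta0 in theta0_list:
        if bounds is None:
            bounds = [(None, None)] * (len(theta0) - 1) + [
                (-_ALPHA_RAW_BOUND, _ALPHA_RAW_BOUND)
            ]
        res = minimize(
            fun,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9},
        )
        objs.append(-float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    return best.x, float(best.fun), bool(best.success), int(best.nit), objs


def _initial_thetas(n_free, restarts, seed, w0_init=None):
    """Deterministic first start (zero weights, w0 = logit(0.1), alpha = 0.5),
    then seeded Gaussian perturbations."""
    if w0_init is None:
        w0_init = float(np.log(0.1 / 0.9))
    base = np.zeros(n_free)
    base[0] = w0_init
    # a_raw = 0 -> alpha = 0.5
    thetas = [base]
    rng = np.random.default_rng(seed)
    for _ in range(restarts - 1):
        t = base + rng.normal(0.0, 0.5, size=n_free)
        thetas.append(t)
    return thetas


def _alpha_from_raw(a_raw: float) -> float:
    return float(np.clip(_sigmoid(np.array([a_raw]))[0], 1e-12, 1.0))


# ---------------------------------------------------------------------------
# estimators


class NullMixture(BaseEstimator):
    """Evidence-free beta-uniform mixture: constant prior sigmoid(w0) and
    Beta(alpha, 1) signal component.  The H0 baseline for every LLR."""

    def __init__(self, restarts: int = 3, max_iter: int = 500,
                 tol: float = 1e-8, random_state: int = 0):
        self.restarts = restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X=None, y=None):
        _, p = _as_arrays(None, y)
        log_p = np.log(p)
        fun = _pack_neg_objective(None, log_p, lam=0.0)
        thetas = _initial_thetas(2, self.restarts, self.random_state)
        theta, neg_obj, conv, nit, objs = _optimize(
            fun, thetas, self.max_iter, self.tol
        )
        self.w0_ = float(theta[0])
        self.alpha_ = _alpha_from_raw(theta[-1])
        self.loglik_ = -neg_obj
        self.converged_ = conv
        self.n_iter_ = nit
        return self

    def log_likelihood(self, y) -> float:
        _, p = _as_arrays(None, y)
        logit = np.full(p.shape, self.w0_)
        return float(_log_mixture_density(logit, self.alpha_, np.log(p)).sum())


class _MixtureBase(BaseEstimator):
    """Shared post-fit surface: priors, densities, LLR, POR/RPOR, ΔLLR."""

    def _column_weights(self) -> np.ndarray:
        raise NotImplementedError

    def _check_X(self, X) -> np.ndarray:
        Xa = X.values.astype(float) if isinstance(X, EvidenceMatrix) else np.asarray(X, dtype=float)
        k = self._column_weights().shape[0]
        if Xa.shape[1] != k:
            raise ValueError(
                f"evidence matrix has {Xa.shape[1]} columns but the model "
                f"was fitted with {k}"
            )
        return Xa

    def prior_prob(self, X) -> np.ndarray:
        """Per-gene Pr(Z_g = 1) under the fitted parameters."""
        Xa = self._check_X(X)
        return _sigmoid(self.w0_ + Xa @ self._column_weights())

    def score_samples(self, X, y) -> np.ndarray:
        """Per-gene log marginal density of the p-values."""
        Xa = self._check_X(X)
        _, p = _as_arrays(None, y)
        logit = self.w0_ + Xa @ self._column_weights()
        return _log_mixture_density(logit, self.alpha_, np.log(p))

    def log_likelihood(self, X, y) -> float:
        return float(self.score_samples(X, y).sum())

    def llr_on(self, X, y, null: NullMixture) -> float:
        """LLR on (possibly held-out) genes against a given null fit."""
        return self.log_likelihood(X, y) - null.log_likelihood(y)

    def posterior_odds(self, X, y) -> np.ndarray:
        """POR = Pr(Z=1 | data) / Pr(Z=0 | data) per gene:
        pi * alpha * p^(alpha-1) / (1 - pi)."""
        Xa = self._check_X(X)
        _, p = _as_arrays(None, y)
        pi = _sigmoid(self.w0_ + Xa @ self._column_weights())
        B = np.exp(np.log(self.alpha_) + (self.alpha_ - 1.0) * np.log(p))
        return pi * B / (1.0 - pi)

    def tf_delta_llr(self, matrix: EvidenceMatrix, y, tf: str) -> float:
        """LLR drop when every evidence column of one TF is zeroed, at the
        trained weights (no refit).  The null term cancels in the difference."""
        zeroed = matrix.zero_tf(tf)  # raises KeyError for unknown TFs
        return self.log_likelihood(matrix, y) - self.log_likelihood(zeroed, y)

    def rank_tfs(self, matrix: EvidenceMatrix, y) -> list[tuple[str, float]]:
        """All TFs ranked by ΔLLR, descending; ties broken by TF name."""
        scores = [(tf, self.tf_delta_llr(matrix, y, tf)) for tf in matrix.tfs]
        return sorted(scores, key=lambda s: (-s[1], s[0]))

    def rpor(self, matrix: EvidenceMatrix, y, tf: str) -> np.ndarray:
        """Per-gene ratio of posterior odds with vs without the TF's evidence;
        the TF -> gene influence score whose top genes form the regulon."""
        full = self.posterior_odds(matrix, y)
        reduced = self.posterior_odds(matrix.zero_tf(tf), y)
        return full / reduced


class PGenMi(_MixtureBase):
    """Free-weight mixture model: one signed weight per evidence column.

    Parameters
    ----------
    reg_lambda : float
        L2 coefficient on the evidence weights (w0 and alpha unpenalized).
    restarts : int
        Optimizer restarts; the first start is deterministic (zero weights),
        the rest are seeded Gaussian perturbations.
    random_state : int
        Seed for the restart perturbations; recorded in the fit result.

    Attributes (after fit)
    ----------------------
    w0_, w_, alpha_ : fitted parameters
    loglik_ : unpenalized log-likelihood at the optimum
    llr_ : loglik_ minus the paired null fit's log-likelihood
    null_ : the fitted :class:`NullMixture`
    """

    def __init__(self, reg_lambda: float = 0.1, restarts: int = 5,
                 max_iter: int = 500, tol: float = 1e-8, random_state: int = 0):
        self.reg_lambda = reg_lambda
        self.restarts = restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _column_weights(self) -> np.ndarray:
        return self.w_

    def fit(self, X, y):
        if isinstance(X, EvidenceMatrix):
            if X.n_columns == 0:
                raise ValueError("evidence matrix has no columns; use NullMixture")
            self.columns_ = list(X.columns)
        else:
            self.columns_ = None
        Xa, p = _as_arrays(X, y)
        if Xa.shape[1] == 0:
            raise ValueError("evidence matrix has no columns; use NullMixture")
        log_p = np.log(p)
        k = Xa.shape[1]
        fun = _pack_neg_objective(Xa, log_p, lam=self.reg_lambda)
        thetas = _initial_thetas(k + 2, self.restarts, self.random_state)
        theta, neg_obj, conv, nit, objs = _optimize(fun, thetas, self.max_iter, self.tol)
        self.w0_ = float(theta[0])
        self.w_ = np.asarray(theta[1:-1], dtype=float)
        self.alpha_ = _alpha_from_raw(theta[-1])
        self.penalized_obj_ = -neg_obj
        self.loglik_ = float(
            _log_mixture_density(self.w0_ + Xa @ self.w_, self.alpha_, log_p).sum()
        )
        self.converged_ = conv
        self.n_iter_ = nit
        self.restart_objectives_ = objs
        self.null_ = NullMixture(
            restarts=self.restarts, max_iter=self.max_iter,
            tol=self.tol, random_state=self.random_state,
        ).fit(None, y)
        self.llr_ = self.loglik_ - self.null_.loglik_
        return self

    @property
    def params_(self) -> PGenMiParams:
        return PGenMiParams(w0=self.w0_, w=self.w_, alpha=self.alpha_)

    def to_result(self) -> FitResult:
        return FitResult(
            params=self.params_,
            loglik=self.loglik_,
            penalized_obj=self.penalized_obj_,
            llr=self.llr_,
            converged=self.converged_,
            null_params=(self.null_.w0_, self.null_.alpha_),
            seed=self.random_state,
            n_iter=self.n_iter_,
            restart_objectives=self.restart_objectives_,
        )


class FwPGenMi(_MixtureBase):
    """Factorized-weight variant: column weight w_tm = w_t * w_m, giving each
    TF a fixed signed role and each mark-change a fixed signed reading.

    For 20 TFs and 4 marks x 2 directions this reduces 160 free evidence
    weights to 28 (20 + 8).  Requires an :class:`EvidenceMatrix` input so
    columns can be matched to TF and mark-change factors.

    ``fix_mark_weights=True`` freezes every w_m at 1, leaving only the per-TF
    weights free (useful for single-mark layouts, where the factorization is
    otherwise scale-degenerate).
    """

    def __init__(self, reg_lambda: float = 0.1, restarts: int = 5,
                 max_iter: int = 500, tol: float = 1e-8, random_state: int = 0,
                 fix_mark_weights: bool = False):
        self.reg_lambda = reg_lambda
        self.restarts = restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.fix_mark_weights = fix_mark_weights

    def _column_weights(self) -> np.ndarray:
        return self.w_tf_[self._ti_] * self.w_mark_[self._mi_]

    def fit(self, X: EvidenceMatrix, y):
        if not isinstance(X, EvidenceMatrix):
            raise TypeError(
                "FwPGenMi requires an EvidenceMatrix so evidence columns can "
                "be matched to TF and mark-change factors"
            )
        if X.n_columns == 0:
            raise ValueError("evidence matrix has no columns; use NullMixture")
        self.columns_ = list(X.columns)
        self.tfs_ = X.tfs
        self.mark_changes_ = X.mark_changes
        tf_pos = {t: i for i, t in enumerate(self.tfs_)}
        mk_pos = {m: i for i, m in enumerate(self.mark_changes_)}
        self._ti_ = np.array([tf_pos[c.tf] for c in X.columns])
        self._mi_ = np.array([mk_pos[c.mark_change] for c in X.columns])
        n_tf, n_mk = len(self.tfs_), len(self.mark_changes_)

        Xa, p = _as_arrays(X, y)
        log_p = np.log(p)
        fun = _pack_neg_objective(
            Xa, log_p, lam=self.reg_lambda, ti=self._ti_, mi=self._mi_,
            n_tf=n_tf, n_mk=n_mk, fix_mark_weights=self.fix_mark_weights,
        )
        n_free = 1 + n_tf + n_mk + 1
        thetas = _initial_thetas(n_free, self.restarts, self.random_state)
        theta, neg_obj, conv, nit, objs = _optimize(fun, thetas, self.max_iter, self.tol)
        self.w0_ = float(theta[0])
        self.w_tf_ = np.asarray(theta[1 : 1 + n_tf], dtype=float)
        self.w_mark_ = (
            np.ones(n_mk) if self.fix_mark_weights
            else np.asarray(theta[1 + n_tf : 1 + n_tf + n_mk], dtype=float)
        )
        self.alpha_ = _alpha_from_raw(theta[-1])
        self.penalized_obj_ = -neg_obj
        w_col = self._column_weights()
        self.loglik_ = float(
            _log_mixture_density(self.w0_ + Xa @ w_col, self.alpha_, log_p).sum()
        )
        self.converged_ = conv
        self.n_iter_ = nit
        self.restart_objectives_ = objs
        self.null_ = NullMixture(
            restarts=self.restarts, max_iter=self.max_iter,
            tol=self.tol, random_state=self.random_state,
        ).fit(None, y)
        self.llr_ = self.loglik_ - self.null_.loglik_
        return self

    @property
    def params_(self) -> FwParams:
        return FwParams(
            w0=self.w0_, tfs=self.tfs_, mark_changes=self.mark_changes_,
            w_tf=self.w_tf_, w_mark=self.w_mark_, alpha=self.alpha_,
        )

    def to_result(self) -> FitResult:
        return FitResult(
            params=self.params_,
            loglik=self.loglik_,
            penalized_obj=self.penalized_obj_,
            llr=self.llr_,
            converged=self.converged_,
            null_params=(self.null_.w0_, self.null_.alpha_),
            seed=self.random_state,
            n_iter=self.n_iter_,
            restart_objectives=self.restart_objectives_,
        )


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit(
    matrix: Optional[EvidenceMatrix],
    pvals: DEPValueVector,
    cfg: Optional[TrainingConfig] = None,
    variant: str = "pgenmi",
) -> FitResult:
    """Train one model variant ("pgenmi", "fw" or "null") and return the
    fitted parameters, log-likelihoods and LLR."""
    cfg = cfg or TrainingConfig()
    common = dict(restarts=cfg.restarts, max_iter=cfg.max_iter,
                  tol=cfg.tol, random_state=cfg.seed)
    if variant == "null":
        est = NullMixture(**common).fit(None, pvals)
        params = PGenMiParams(w0=est.w0_, w=np.zeros(0), alpha=est.alpha_)
        return FitResult(
            params=params, loglik=est.loglik_, penalized_obj=est.loglik_,
            llr=0.0, converged=est.converged_,
            null_params=(est.w0_, est.alpha_), seed=cfg.seed,
            n_iter=est.n_iter_,
        )
    if variant == "pgenmi":
        est = PGenMi(reg_lambda=cfg.reg_lambda, **common)
    elif variant == "fw":
        est = FwPGenMi(reg_lambda=cfg.reg_lambda, **common)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    est.fit(matrix, pvals)
    result = est.to_result()
    result.estimator = est  # convenience back-reference, not part of the dataclass
    return result


def _estimator_from_result(fit_result: FitResult, matrix: EvidenceMatrix):
    est = getattr(fit_result, "estimator", None)
    if est is not None:
        return est
    params = fit_result.params
    if isinstance(params, FwParams):
        est = FwPGenMi()
        est.tfs_ = params.tfs
        est.mark_changes_ = params.mark_changes
        tf_pos = {t: i for i, t in enumerate(params.tfs)}
        mk_pos = {m: i for i, m in enumerate(params.mark_changes)}
        est._ti_ = np.array([tf_pos[c.tf] for c in matrix.columns])
        est._mi_ = np.array([mk_pos[c.mark_change] for c in matrix.columns])
        est.w_tf_, est.w_mark_ = params.w_tf, params.w_mark
    else:
        est = PGenMi()
        est.w_ = params.w
    est.w0_ = params.w0
    est.alpha_ = params.alpha
    return est


def tf_delta_llr(fit_result: FitResult, matrix: EvidenceMatrix,
                 pvals: DEPValueVector, tf: str) -> float:
    """LLR contribution of one TF: full-matrix LLR minus the LLR with that
    TF's evidence zeroed, evaluated at the trained weights."""
    est = _estimator_from_result(fit_result, matrix)
    return est.tf_delta_llr(matrix, pvals, tf)


def posterior_odds(fit_result: FitResult, matrix: EvidenceMatrix,
                   pvals: DEPValueVector, gene: str) -> float:
    """Posterior odds Pr(Z_g=1 | data) / Pr(Z_g=0 | data) for one gene."""
    est = _estimator_from_result(fit_result, matrix)
    g = matrix.gene_index(gene)
    return float(est.posterior_odds(matrix, pvals)[g])


def rpor(fit_result: FitResult, matrix: EvidenceMatrix,
         pvals: DEPValueVector, tf: str, gene: str) -> float:
    """Ratio of posterior odds with vs without one TF's evidence for one gene."""
    est = _estimator_from_result(fit_result, matrix)
    g = matrix.gene_index(gene)
    return float(est.rpor(matrix, pvals, tf)[g])
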