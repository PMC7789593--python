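"""Cross-validation, permutation nulls, TF-profile similarity, enrichment
and gene signatures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import ttest_1samp

from pgenmi.containers import DEPValueVector, EvidenceColumnKey, EvidenceMatrix
from pgenmi.evaluation import (
    CVResult,
    SplitScheme,
    cross_validate,
    gene_signature,
    hypergeometric_enrichment,
    jaccard_similarity,
    paired_strategy_wins,
    select_distinct_tfs,
    shuffle_evidence,
    shuffled_null,
    tf_feature_vectors,
    top_rank_frequency,
)
from pgenmi.model import PGenMi, PGenMiParams, TrainingConfig
from pgenmi.simulate import SimulationSpec, simulate_dataset


class TestSplitScheme:
    def test_partitions_disjoint_and_cover(self):
        scheme = SplitScheme(fractions=(0.72, 0.18, 0.10), n_repeats=3, seed=1)
        tr, va, te = scheme.partition(1000, repeat=0)
        combined = np.concatenate([tr, va, te])
        assert len(combined) == 1000
        assert len(set(combined.tolist())) == 1000
        assert len(tr) == 720 and len(va) == 180 and len(te) == 100

    def test_same_seed_same_partition(self):
        scheme = SplitScheme(fractions=(0.8, 0.0, 0.2), n_repeats=1, seed=9)
        a = scheme.partition(500, 0)
        b = scheme.partition(500, 0)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            SplitScheme(fractions=(0.5, 0.2, 0.2))


def _simulated(n_genes, w, seed, density=0.05, alpha=0.2, w0=-2.0):
    k = len(w)
    labels = [f"H3K27ac-{d}" for d in ("up", "down")]
    n_tfs = k // len(labels)
    spec = SimulationSpec(
        n_genes=n_genes, n_tfs=n_tfs, mark_changes=labels,
        evidence_density=density,
        true_params=PGenMiParams(w0=w0, w=np.asarray(w, dtype=float), alpha=alpha),
        seed=seed,
    )
    return simulate_dataset(spec)


class TestCrossValidate:
    def test_full_data_llr_matches_trained_model(self):
        """Evaluating a trained model on all genes reproduces its training
        LLR (the test-fraction-1 limiting case)."""
        data = _simulated(3000, [3.0, 0, 0, 0], seed=2)
        model = PGenMi(reg_lambda=0.1, restarts=1, random_state=0).fit(
            data.matrix, data.pvals
        )
        assert model.llr_on(data.matrix, data.pvals, model.null_) == pytest.approx(model.llr_)

    def test_null_data_mean_test_llr_not_positive(self):
        data = _simulated(3000, [0.0] * 4, seed=5)
        scheme = SplitScheme(fractions=(0.8, 0.0, 0.2), n_repeats=20, seed=5)
        cv = cross_validate({1000: data.matrix}, data.pvals, None, scheme,
                            lambda_grid=(0.1,), cfg=TrainingConfig(restarts=1))
        llrs = cv.records["test_llr_total"].to_numpy()
        t = ttest_1samp(llrs, 0.0, alternative="greater")
        assert t.pvalue > 0.05

    def test_informative_matrix_beats_shuffled_in_paired_repeats(self):
        data = _simulated(3000, [3.0, 2.0, 0, 0], seed=6)
        rng = np.random.default_rng(0)
        shuffled = shuffle_evidence(data.matrix, rng)
        scheme = SplitScheme(fractions=(0.72, 0.18, 0.10), n_repeats=50, seed=6)
        cfg = TrainingConfig(restarts=1)
        cv_real = cross_validate({1000: data.matrix}, data.pvals, None, scheme,
                                 lambda_grid=(0.1,), cfg=cfg)
        cv_shuf = cross_validate({1000: shuffled}, data.pvals, None, scheme,
                                 lambda_grid=(0.1,), cfg=cfg)
        wins, losses, ties = paired_strategy_wins(cv_real, cv_shuf)
        assert wins >= 0.9 * scheme.n_repeats

    def test_hyperparameter_mode_selects_over_grid(self):
        data = _simulated(2000, [3.0, 0.0], seed=7)
        scheme = SplitScheme(fractions=(0.8, 0.0, 0.2), n_repeats=3, seed=7)
        cv = cross_validate({500: data.matrix, 1000: data.matrix}, data.pvals,
                            None, scheme, lambda_grid=(0.01, 1.0),
                            cfg=TrainingConfig(restarts=1))
        assert cv.mode == "hyperparameter"
        assert cv.best_d in (500, 1000)
        assert cv.best_lambda in (0.01, 1.0)
        # 3 repeats x 2 d x 2 lambda
        assert len(cv.records) == 12

    def test_gene_universe_mismatch_rejected(self):
        data = _simulated(100, [1.0, 0.0], seed=1)
        other = _simulated(100, [1.0, 0.0], seed=2)
        renamed = EvidenceMatrix(
            [g + "_x" for g in other.matrix.gene_ids],
            list(other.matrix.columns), other.matrix.values,
        )
        scheme = SplitScheme(fractions=(0.8, 0.0, 0.2), n_repeats=1, seed=0)
        with pytest.raises(ValueError, match="different genes"):
            cross_validate({1: data.matrix, 2: renamed}, data.pvals, None, scheme)

    def test_fixed_seed_reproducible(self):
        data = _simulated(1000, [2.0, 0.0], seed=3)
        scheme = SplitScheme(fractions=(0.8, 0.0, 0.2), n_repeats=2, seed=3)
        cfg = TrainingConfig(restarts=1)
        a = cross_validate({1000: data.matrix}, data.pvals, None, scheme,
                           lambda_grid=(0.1,), cfg=cfg)
        b = cross_validate({1000: data.matrix}, data.pvals, None, scheme,
                           lambda_grid=(0.1,), cfg=cfg)
        assert a.records.equals(b.records)
        assert a.summary == b.summary


class TestShuffledNull:
    def test_all_zero_matrix_gives_zero_llrs(self):
        cols = [EvidenceColumnKey("T", "H3K27ac", "up")]
        matrix = EvidenceMatrix(
            [f"g{i}" for i in range(200)], cols, np.zeros((200, 1), dtype=np.uint8)
        )
        rng = np.random.default_rng(0)
        pvals = DEPValueVector([f"g{i}" for i in range(200)], rng.random(200))
        dist = shuffled_null(matrix, pvals, TrainingConfig(restarts=1), n_perm=3, seed=0)
        np.testing.assert_allclose(dist.llrs, 0.0, atol=1e-6)

    def test_column_marginals_preserved(self):
        data = _simulated(500, [1.0, 0.0, 0.0, 0.0], seed=4)
        rng = np.random.default_rng(1)
        shuffled = shuffle_evidence(data.matrix, rng)
        np.testing.assert_array_equal(
            shuffled.values.sum(axis=0), data.matrix.values.sum(axis=0)
        )
        assert shuffled.columns == data.matrix.columns

    def test_observed_exceeds_all_permutations_on_informative_data(self):
        data = _simulated(2000, [3.0, 0.0], seed=8)
        cfg = TrainingConfig(reg_lambda=0.1, restarts=1, seed=0)
        observed = PGenMi(reg_lambda=0.1, restarts=1, random_state=0).fit(
            data.matrix, data.pvals
        )
        dist = shuffled_null(data.matrix, data.pvals, cfg, n_perm=50, seed=0)
        assert observed.llr_ > dist.llrs.max()


class TestTFSimilarity:
    def test_feature_vector_is_or_of_columns(self):
        rng = np.random.default_rng(2)
        cols = [
            EvidenceColumnKey(tf, m, d)
            for tf in ("A", "B")
            for m in ("H3K27ac", "H3K4me1")
            for d in ("up", "down")
        ]
        values = (rng.random((40, 8)) < 0.3).astype(np.uint8)
        matrix = EvidenceMatrix([f"g{i}" for i in range(40)], cols, values)
        feats = tf_feature_vectors(matrix)
        for tf in ("A", "B"):
            idx = [i for i, c in enumerate(cols) if c.tf == tf]
            manual = np.zeros(40, dtype=np.uint8)
            for g in range(40):
                manual[g] = max(values[g, i] for i in idx)
            np.testing.assert_array_equal(feats[tf], manual)

    def test_single_column_tf_passthrough(self):
        cols = [EvidenceColumnKey("A", "TFBS", "present")]
        values = np.array([[1], [0], [1]], dtype=np.uint8)
        matrix = EvidenceMatrix(["g1", "g2", "g3"], cols, values)
        np.testing.assert_array_equal(tf_feature_vectors(matrix)["A"], [1, 0, 1])

    @pytest.mark.parametrize(
        "u,v,expected",
        [
            ([1, 1, 0], [1, 1, 0], 1.0),
            ([1, 0, 0], [0, 1, 0], 0.0),
            ([1, 1, 0, 0], [1, 0, 1, 0], 1 / 3),
            ([0, 0], [0, 0], 0.0),  # all-zero convention
        ],
    )
    def test_jaccard_examples(self, u, v, expected):
        assert jaccard_similarity(u, v) == pytest.approx(expected)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=1, max_size=30))
    def test_jaccard_symmetric_and_bounded(self, pairs):
        u = [a for a, _ in pairs]
        v = [b for _, b in pairs]
        s = jaccard_similarity(u, v)
        assert 0.0 <= s <= 1.0
        assert s == jaccard_similarity(v, u)
        if any(u):
            assert jaccard_similarity(u, u) == 1.0

    def test_select_distinct_excludes_identical_profiles(self):
        cols_f = [EvidenceColumnKey("F1", "TFBS", "present"),
                  EvidenceColumnKey("F2", "TFBS", "present")]
        cols_r = [EvidenceColumnKey("R1", "TFBS", "present")]
        genes = [f"g{i}" for i in range(6)]
        ref_vec = np.array([1, 1, 0, 0, 0, 0], dtype=np.uint8)
        f_values = np.stack([ref_vec, np.array([0, 0, 0, 1, 1, 1], dtype=np.uint8)], axis=1)
        foreign = EvidenceMatrix(genes, cols_f, f_values)
        reference = EvidenceMatrix(genes, cols_r, ref_vec[:, None])
        # F1 identical to R1 (Jaccard 1) is excluded; disjoint F2 is kept
        assert select_distinct_tfs(foreign, reference, cutoff=0.2) == ["F2"]

    def test_select_distinct_hand_scores(self):
        genes = [f"g{i}" for i in range(5)]
        ref = EvidenceMatrix(
            genes, [EvidenceColumnKey("R", "TFBS", "present")],
            np.array([[1], [1], [0], [0], [0]], dtype=np.uint8),
        )
        # similarities to R: A 2/2=1.0, B 1/3, C 0
        f_cols = [EvidenceColumnKey(t, "TFBS", "present") for t in ("A", "B", "C")]
        f_vals = np.array(
            [[1, 1, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [0, 0, 0]], dtype=np.uint8
        )
        foreign = EvidenceMatrix(genes, f_cols, f_vals)
        assert select_distinct_tfs(foreign, ref, cutoff=0.5) == ["B", "C"]
        assert select_distinct_tfs(foreign, ref, cutoff=0.2) == ["C"]

    def test_empty_foreign_set(self):
        genes = ["g1"]
        ref = EvidenceMatrix(
            genes, [EvidenceColumnKey("R", "TFBS", "present")],
            np.array([[1]], dtype=np.uint8),
        )
        empty = EvidenceMatrix(genes, [], np.zeros((1, 0), dtype=np.uint8))
        assert select_distinct_tfs(empty, ref, cutoff=0.2) == []


class TestTopRankFrequency:
    def _target_and_pool(self, n_genes=2000, n_pool=6, seed=0, informative_target=True):
        w_target = 3.0 if informative_target else 0.0
        data = _simulated(n_genes, [w_target, 0.0], seed=seed)
        target = data.matrix.select_columns([0, 1])
        rng = np.random.default_rng(seed + 1)
        pool_cols = [EvidenceColumnKey(f"D{i:02d}", "H3K27ac", "up") for i in range(n_pool)]
        pool_vals = np.zeros((n_genes, n_pool), dtype=np.uint8)
        pool = EvidenceMatrix(list(data.matrix.gene_ids), pool_cols, pool_vals)
        return target, pool, data.pvals

    def test_informative_target_beats_empty_distractors(self):
        target, pool, pvals = self._target_and_pool(informative_target=True)
        res = top_rank_frequency(target, pool, pvals,
                                 TrainingConfig(restarts=1), n_iter=5,
                                 pool_size=3, seed=0)
        assert res.frequency == 1.0

    def test_single_iteration_is_binary(self):
        target, pool, pvals = self._target_and_pool()
        res = top_rank_frequency(target, pool, pvals,
                                 TrainingConfig(restarts=1), n_iter=1,
                                 pool_size=3, seed=1)
        assert res.frequency in (0.0, 1.0)

    def test_uninformative_target_rarely_tops_informative_distractors(self):
        n_genes = 2000
        data = _simulated(n_genes, [0.0, 0.0], seed=9)
        target = data.matrix.select_columns([0, 1])
        # distractors carry the real signal: regenerate p-values driven by D00
        pool_cols = [EvidenceColumnKey(f"D{i:02d}", "H3K27ac", "up") for i in range(6)]
        rng = np.random.default_rng(10)
        pool_vals = (rng.random((n_genes, 6)) < 0.1).astype(np.uint8)
        pool = EvidenceMatrix(list(data.matrix.gene_ids), pool_cols, pool_vals)
        logit = -2.0 + 4.0 * pool_vals[:, 0]
        pi = 1 / (1 + np.exp(-logit))
        z = rng.random(n_genes) < pi
        p = np.where(z, rng.beta(0.2, 1, n_genes), rng.random(n_genes))
        pvals = DEPValueVector(list(data.matrix.gene_ids), np.clip(p, 1e-12, 1))
        res = top_rank_frequency(target, pool, pvals,
                                 TrainingConfig(restarts=1), n_iter=10,
                                 pool_size=4, seed=2)
        assert res.frequency <= 0.2

    def test_pool_size_validation(self):
        target, pool, pvals = self._target_and_pool()
        with pytest.raises(ValueError, match="pool_size"):
            top_rank_frequency(target, pool, pvals, n_iter=1, pool_size=99)


class TestHypergeometricEnrichment:
    def test_exhaustive_enumeration_case(self):
        # universe 10, both sets 5, overlap 5: only 1 of C(10,5) draws
        assert hypergeometric_enrichment(5, 5, 5, 10) == pytest.approx(1 / 252)

    def test_zero_overlap_inclusive_tail_is_one(self):
        assert hypergeometric_enrichment(50, 80, 0, 1000) == pytest.approx(1.0)

    def test_monte_carlo_cross_check(self):
        """Exact tail vs simulated set-overlap frequencies (3 SE band)."""
        universe, na, nb, k = 60, 15, 20, 8
        p_exact = hypergeometric_enrichment(na, nb, k, universe)
        rng = np.random.default_rng(0)
        n_draws = 100_000
        hits = 0
        b_set = np.zeros(universe, dtype=bool)
        b_set[:nb] = True
        for _ in range(n_draws):
            draw = rng.choice(universe, size=na, replace=False)
            if b_set[draw].sum() >= k:
                hits += 1
        p_mc = hits / n_draws
        se = np.sqrt(p_exact * (1 - p_exact) / n_draws)
        assert abs(p_mc - p_exact) <= 3 * se

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(10, 10, 11, 100)
        with pytest.raises(ValueError):
            hypergeometric_enrichment(200, 10, 5, 100)


class TestGeneSignature:
    def test_single_tf_ranking_matches_rpor_order(self):
        rpor = {"A": {"g1": 5.0, "g2": 1.0, "g3": 3.0}}
        assert gene_signature(rpor, ["A"], n=3) == ["g1", "g3", "g2"]

    def test_all_unity_rpor_scores_one(self):
        rpor = {"A": {"g1": 1.0, "g2": 1.0}, "B": {"g1": 1.0, "g2": 1.0}}
        ranked = gene_signature(rpor, ["A", "B"], n=2)
        assert ranked == ["g1", "g2"]  # ties broken by gene id

    def test_two_tf_product_hand_case(self):
        rpor = {
            "A": {"g1": 2.0, "g2": 4.0, "g3": 1.0},
            "B": {"g1": 3.0, "g2": 1.0, "g3": 5.0},
        }
        # products: g1=6, g2=4, g3=5
        assert gene_signature(rpor, ["A", "B"], n=3) == ["g1", "g3", "g2"]
        assert gene_signature(rpor, ["A", "B"], n=2) == ["g1", "g3"]

    def test_missing_tf_table_rejected(self):
        with pytest.raises(KeyError):
            gene_signature({"A": {"g": 1.0}}, ["A", "Z"], n=1)
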