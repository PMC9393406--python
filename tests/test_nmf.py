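import itertools

import numpy as np
import pytest

from cortexlv import assembly, nmf, synthetic
from cortexlv.errors import ConfigError


def planted_matrix(n_v=60, n_s=40, k=4, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    W = synthetic.generate_components(n_v, k, 0.0, seed)
    H = rng.uniform(0.5, 1.5, size=(k, n_s))
    X = W @ H
    if noise:
        X = np.maximum(X + rng.normal(0, noise, X.shape), 0)
    return X, W, H


class TestNNDSVDInit:
    def test_diagonal_matrix_splits_axes(self):
        # hand SVD of diag(2, 1): singular triplets are the unit axes
        W0, H0 = nmf.nndsvd_init(np.diag([2.0, 1.0]), k=2)
        np.testing.assert_allclose(W0, [[np.sqrt(2), 0], [0, 1]], atol=1e-12)
        np.testing.assert_allclose(H0, [[np.sqrt(2), 0], [0, 1]], atol=1e-12)

    def test_rank_one_outer_product_recovered(self):
        u = np.array([1.0, 2.0, 0.5, 0.0])
        v = np.array([3.0, 1.0, 2.0])
        X = np.outer(u, v)
        W0, H0 = nmf.nndsvd_init(X, k=1)
        np.testing.assert_allclose(W0 @ H0, X, atol=1e-10)

    def test_factors_never_negative(self):
        rng = np.random.default_rng(4)
        X = np.abs(rng.normal(size=(30, 20)))
        W0, H0 = nmf.nndsvd_init(X, k=5)
        assert W0.min() >= 0 and H0.min() >= 0

    def test_k_out_of_range_is_error(self):
        with pytest.raises(ConfigError):
            nmf.nndsvd_init(np.ones((3, 3)), k=4)


class TestFitNMF:
    def test_noiseless_planted_rank_recovered(self):
        X, W, H = planted_matrix()
        model = nmf.fit_nmf(X, k=4, tol=1e-10, max_iter=300)
        rel_err = model.recon_error / np.linalg.norm(X)
        assert rel_err < 1e-6
        assert model.W.min() >= 0 and model.H.min() >= 0

    def test_objective_monotone_non_increasing(self):
        X, *_ = planted_matrix(seed=3, noise=0.1)
        model = nmf.fit_nmf(X, k=4)
        obj = model.objective_history
        assert np.all(np.diff(obj) <= 1e-9 * np.maximum(obj[:-1], 1e-12))

    def test_component_recovery_under_noise(self):
        X, W, _ = planted_matrix(n_v=200, n_s=100, seed=5, noise=0.05)
        model = nmf.fit_nmf(X, k=4)
        _, sims = nmf.match_components(W, model.W)
        assert sims.mean() > 0.95

    def test_nonfinite_input_rejected(self):
        X = np.ones((4, 4))
        X[0, 0] = np.nan
        with pytest.raises(Exception, match="finite"):
            nmf.fit_nmf(X, k=2)

    def test_objective_near_random_restart_oracle(self):
        # global-ish oracle: best of 50 random restarts via multiplicative
        # NMF from scratch on tiny problems
        from sklearn.decomposition import NMF as SkNMF

        rng = np.random.default_rng(8)
        for k in (2, 3):
            X = np.abs(rng.normal(size=(20, 12))) + 0.1
            model = nmf.fit_nmf(X, k=k, tol=1e-9, max_iter=1000)
            best = np.inf
            for r in range(50):
                sk = SkNMF(
                    n_components=k, init="random", random_state=r,
                    max_iter=2000, tol=1e-9,
                )
                Wr = sk.fit_transform(X)
                best = min(best, np.linalg.norm(X - Wr @ sk.components_))
            assert model.recon_error <= best * 1.01


class TestMatchComponents:
    def test_column_permutation_recovered(self):
        rng = np.random.default_rng(0)
        W = np.abs(rng.normal(size=(50, 5)))
        perm = np.array([3, 0, 4, 1, 2])
        assignment, sims = nmf.match_components(W, W[:, perm])
        # column j of W equals column assignment[j] of the permuted matrix
        np.testing.assert_array_equal(np.argsort(perm), assignment)
        np.testing.assert_allclose(sims, 1.0, atol=1e-12)

    def test_orthogonal_replacement_column_scores_zero(self):
        rng = np.random.default_rng(1)
        k = 4
        W = np.zeros((40, k))
        for c in range(k):
            W[10 * c : 10 * (c + 1), c] = 1.0
        W_b = W.copy()
        W_b[:, 2] = 0.0
        W_b[10 * 2 : 10 * 3, 2] = 0.0
        W_b[:, 2] = np.abs(rng.normal(size=40)) * (W.sum(axis=1) == 0)
        assignment, sims = nmf.match_components(W, W_b)
        assert (sims > 0.99).sum() == k - 1
        assert sims.min() < 0.1

    def test_brute_force_assignment_agreement(self):
        # optimal assignment equals exhaustive search over all k! pairings
        rng = np.random.default_rng(2)
        for trial in range(5):
            Wa = np.abs(rng.normal(size=(15, 4)))
            Wb = np.abs(rng.normal(size=(15, 4)))
            assignment, sims = nmf.match_components(Wa, Wb)
            sim = (Wa / np.linalg.norm(Wa, axis=0)).T @ (
                Wb / np.linalg.norm(Wb, axis=0)
            )
            best = max(
                sum(sim[i, p[i]] for i in range(4))
                for p in itertools.permutations(range(4))
            )
            assert sum(sims) == pytest.approx(best, abs=1e-12)

    def test_k1_single_cosine(self):
        a = np.array([[1.0], [0.0]])
        b = np.array([[1.0], [1.0]])
        _, sims = nmf.match_components(a, b)
        assert sims[0] == pytest.approx(1 / np.sqrt(2))

    def test_shape_mismatch_is_error(self):
        with pytest.raises(ConfigError):
            nmf.match_components(np.ones((5, 2)), np.ones((5, 3)))


def _tiny_stacked(n_v=60, n_s=16, k=3, seed=0, noise=0.0):
    cfg = synthetic.CohortConfig(
        n_vertices=n_v, n_subjects=n_s, k_true=k, noise_sd=noise,
        scanner_offset_sd=0.0, overlap_frac=0.0,
    )
    cohort = synthetic.simulate_cohort(cfg, seed=seed)
    tables = [cohort.metric_tables[m] for m in assembly.METRICS]
    return assembly.assemble(tables), cohort


class TestSplitHalfStability:
    def test_identical_halves_have_stability_one(self):
        stacked, _ = _tiny_stacked()
        # duplicate the same subjects into both halves by stacking the
        # matrix twice with relabeled subjects
        dup = assembly.StackedInput(
            matrix=np.hstack([stacked.matrix, stacked.matrix]),
            shift=stacked.shift,
            column_index=stacked.column_index
            + [(f"dup_{s}", m) for s, m in stacked.column_index],
            mask=stacked.mask,
            scanner_labels=stacked.scanner_labels * 2,
        )
        fa = nmf.fit_nmf(stacked.matrix, 3, tol=1e-8)
        _, sims = nmf.match_components(fa.W, fa.W)
        np.testing.assert_allclose(sims, 1.0, atol=1e-6)

    def test_noiseless_planted_k_highly_stable(self):
        # the min-shift leaves component profiles highly correlated, so the
        # optimum is flat and halves can differ by tiny mixings: stability
        # approaches but does not reach 1 (measured ~0.98 here)
        stacked, _ = _tiny_stacked(noise=0.0)
        curve = nmf.split_half_stability(
            stacked, [3], n_splits=3, seed=0, tol=1e-10, max_iter=1000
        )
        assert curve.stability[0] > 0.95

    def test_same_seed_identical_curve(self):
        stacked, _ = _tiny_stacked(noise=0.05)
        a = nmf.split_half_stability(stacked, [2, 3], n_splits=2, seed=5)
        b = nmf.split_half_stability(stacked, [2, 3], n_splits=2, seed=5)
        np.testing.assert_array_equal(a.stability, b.stability)
        np.testing.assert_array_equal(a.recon_error, b.recon_error)

    def test_planted_structure_more_stable_than_noise(self):
        # iid non-negative noise still shares its positive mean direction
        # across halves, so its stability is well above 0; planted structure
        # must exceed it by a material margin
        cfg = synthetic.CohortConfig(
            n_vertices=500, n_subjects=100, k_true=5, noise_sd=0.05,
            scanner_offset_sd=0.0,
        )
        cohort = synthetic.simulate_cohort(cfg, seed=0)
        stacked = assembly.assemble(
            [cohort.metric_tables[m] for m in assembly.METRICS]
        )
        rng = np.random.default_rng(13)
        noise_only = assembly.StackedInput(
            matrix=np.abs(rng.normal(size=stacked.matrix.shape)),
            shift=0.0,
            column_index=stacked.column_index,
            mask=stacked.mask,
            scanner_labels=stacked.scanner_labels,
        )
        ks = [5]
        planted = nmf.split_half_stability(
            stacked, ks, n_splits=3, seed=1, max_iter=600
        )
        null = nmf.split_half_stability(
            noise_only, ks, n_splits=3, seed=1, max_iter=600
        )
        assert planted.stability[0] - null.stability[0] > 0.1


class TestSelectRank:
    def _curve(self, ks, stab, err):
        ks = np.asarray(ks)
        err = np.asarray(err, float)
        grad = np.zeros(len(ks))
        if len(ks) > 1:
            grad[:-1] = np.diff(err) / np.diff(ks.astype(float))
            grad[-1] = grad[-2]
        return nmf.StabilityCurve(
            ks=ks, stability=np.asarray(stab, float),
            recon_error=err, error_gradient=grad,
        )

    def test_planted_elbow_with_stability_peak(self):
        curve = self._curve(
            [2, 3, 4, 5, 6],
            [0.90, 0.93, 0.99, 0.90, 0.88],
            [100.0, 60.0, 20.0, 19.5, 19.0],
        )
        assert nmf.select_rank(curve) == 4

    def test_flat_curves_return_max_k(self):
        curve = self._curve([2, 3, 4], [0.9, 0.9, 0.9], [5.0, 5.0, 5.0])
        with pytest.warns(UserWarning):
            assert nmf.select_rank(curve) == 4

    def test_single_candidate_returned(self):
        curve = self._curve([7], [0.5], [3.0])
        assert nmf.select_rank(curve) == 7

    def test_empty_intersection_falls_back_to_argmax(self):
        # stability peaks where the gradient is still steep
        curve = self._curve(
            [2, 3, 4], [0.99, 0.80, 0.70], [100.0, 50.0, 25.0]
        )
        with pytest.warns(UserWarning, match="falling back"):
            assert nmf.select_rank(curve) == 2


class TestVertexLabelsAndWeights:
    def test_threshold_rule_arithmetic(self):
        W = np.zeros((5, 1))
        W[:, 0] = [4.0, 1.0, 0.9, 2.0, 3.9]
        memberships, winners = nmf.assign_vertex_labels(W, threshold_frac=0.25)
        hit = [v for v, s in enumerate(memberships) if 0 in s]
        assert hit == [0, 1, 3, 4]

    def test_disjoint_parcels_winner_partition(self):
        W = synthetic.generate_components(100, 4, 0.0, seed=2)
        _, winners = nmf.assign_vertex_labels(W)
        truth = np.argmax(W, axis=1)
        np.testing.assert_array_equal(winners, truth)

    def test_threshold_one_keeps_only_argmax(self):
        rng = np.random.default_rng(6)
        W = np.abs(rng.normal(size=(30, 3)))
        memberships, _ = nmf.assign_vertex_labels(W, threshold_frac=1.0)
        for c in range(3):
            members = [v for v, s in enumerate(memberships) if c in s]
            assert members == [int(np.argmax(W[:, c]))]

    def test_all_zero_component_warns(self):
        W = np.ones((4, 2))
        W[:, 1] = 0.0
        with pytest.warns(UserWarning, match="all-zero"):
            memberships, _ = nmf.assign_vertex_labels(W)
        assert all(1 not in s for s in memberships)

    def test_weight_reshape_is_lossless(self):
        stacked, cohort = _tiny_stacked()
        model = nmf.fit_nmf(stacked, k=3)
        weights = nmf.extract_subject_metric_weights(model, stacked.column_index)
        assert weights.shape == (16, 3 * 5)
        # round trip back to H layout
        n = len(weights)
        for c in range(3):
            for mi, metric in enumerate(assembly.METRICS):
                np.testing.assert_array_equal(
                    weights[f"C{c+1}_{metric}"].to_numpy(),
                    model.H[c, mi * n : (mi + 1) * n],
                )

    def test_k10_five_metrics_give_50_columns(self, default_stacked):
        model = nmf.NMFModel(
            W=np.zeros((5, 10)),
            H=np.zeros((10, len(default_stacked.column_index))),
            k=10, recon_error=0.0, objective_history=np.array([0.0]),
            iterations=0, seed=0,
        )
        weights = nmf.extract_subject_metric_weights(
            model, default_stacked.column_index
        )
        assert weights.shape == (398 if weights.shape[0] == 398 else 400, 50)
        assert weights.shape[1] == 50

    def test_single_metric_k1_equals_h_transposed(self):
        H = np.array([[1.0, 2.0, 3.0]])
        model = nmf.NMFModel(
            W=np.zeros((4, 1)), H=H, k=1,
            recon_error=0.0, objective_history=np.array([0.0]),
            iterations=0, seed=0,
        )
        weights = nmf.extract_subject_metric_weights(
            model, [("a", "CT"), ("b", "CT"), ("c", "CT")]
        )
        np.testing.assert_array_equal(weights.to_numpy(), H.T)
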