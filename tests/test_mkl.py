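"""Tests of the KOMD solver and EasyMKL kernel combination."""

import itertools

import numpy as np
import pytest

from mklfusion import (
    MKLModel,
    build_kernel_set,
    easymkl_fit,
    extract_primal_weights,
    generate_cohort,
    mkl_decision_scores,
    solve_komd,
    SyntheticSpec,
)
from mklfusion.kernels import GramMatrix, KernelSet


def _komd_objective(K, y, lam):
    YKY = K * np.outer(y, y)

    def f(g):
        return (1 - lam) * g @ YKY @ g + lam * g @ g

    return f


def _bisimplex_grid(n_pos, n_neg, step):
    """Every bi-simplex point on a fixed grid (brute-force oracle)."""
    def simplex(n):
        ticks = int(round(1 / step))
        for comp in itertools.combinations_with_replacement(range(n), ticks):
            v = np.zeros(n)
            for i in comp:
                v[i] += step
            yield v

    for p in simplex(n_pos):
        for q in simplex(n_neg):
            yield np.concatenate([p, q])


class TestSolveKomd:
    def test_one_subject_per_class_forces_unit_gamma(self, rng):
        K = rng.standard_normal((2, 3))
        K = K @ K.T
        g = solve_komd(K, np.array([1.0, -1.0]), 0.3)
        assert np.allclose(g, [1.0, 1.0], atol=1e-8)

    def test_pure_ridge_returns_per_class_uniform(self):
        # per-class sums are constrained to 1, so uniform = 0.5 with 2 per class
        g = solve_komd(np.eye(4), np.array([1.0, 1.0, -1.0, -1.0]), 1.0)
        assert np.allclose(g, 0.5 * np.ones(4), atol=1e-8)

    @pytest.mark.parametrize("lam", [0.0, 0.5, 1.0])
    def test_beats_brute_force_grid(self, lam, rng):
        X = rng.standard_normal((4, 3))
        K = X @ X.T
        y = np.array([1.0, 1.0, -1.0, -1.0])
        g = solve_komd(K, y, lam)
        f = _komd_objective(K, y, lam)
        grid_best = min(f(v) for v in _bisimplex_grid(2, 2, 0.05))
        assert f(g) <= grid_best + 1e-9

    def test_beats_random_bisimplex_points(self, rng):
        X = rng.standard_normal((8, 5))
        K = X @ X.T
        y = np.array([1.0] * 3 + [-1.0] * 5)
        g = solve_komd(K, y, 0.2)
        f = _komd_objective(K, y, 0.2)
        fg = f(g)
        d = rng.dirichlet(np.ones(3), size=10_000)
        e = rng.dirichlet(np.ones(5), size=10_000)
        pts = np.hstack([d, e])
        YKY = K * np.outer(y, y)
        vals = 0.8 * np.einsum("bi,ij,bj->b", pts, YKY, pts) + 0.2 * np.sum(pts**2, axis=1)
        assert fg <= vals.min() + 1e-9

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="class"):
            solve_komd(np.eye(3), np.ones(3), 0.5)

    def test_indefinite_gram_raises_with_eigenvalue(self):
        K = np.array([[1.0, 0.0], [0.0, -2.0]])
        with pytest.raises(ValueError, match="eigenvalue"):
            solve_komd(K, np.array([1.0, -1.0]), 0.5)

    def test_deterministic(self, rng):
        X = rng.standard_normal((6, 4))
        K = X @ X.T
        y = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0])
        assert np.array_equal(solve_komd(K, y, 0.1), solve_komd(K, y, 0.1))


def _kernel_set_from_arrays(arrays, scale_factors=None):
    n = arrays[0].shape[0]
    ids = tuple(f"s{i}" for i in range(n))
    scale_factors = scale_factors or [1.0] * len(arrays)
    entries = [
        (f"m{r}", GramMatrix(K, ids, ids, f"m{r}", scale_factor=c), None)
        for r, (K, c) in enumerate(zip(arrays, scale_factors))
    ]
    return KernelSet(entries)


class TestEasyMKL:
    def test_single_modality_gets_full_weight(self, rng):
        X = rng.standard_normal((6, 3))
        kset = _kernel_set_from_arrays([X @ X.T])
        y = np.array([1.0] * 3 + [-1.0] * 3)
        model = easymkl_fit(kset, y, 0.1)
        assert np.allclose(model.eta, [1.0])

    def test_identical_kernels_share_weight_equally(self, rng):
        X = rng.standard_normal((6, 3))
        K = X @ X.T
        kset = _kernel_set_from_arrays([K, K.copy()])
        y = np.array([1.0] * 3 + [-1.0] * 3)
        model = easymkl_fit(kset, y, 0.1)
        assert np.allclose(model.eta, [0.5, 0.5], atol=1e-10)

    def test_near_zero_kernel_gets_near_zero_weight(self):
        """A label-aligned kernel against an epsilon-diagonal stand-in for an
        all-zero-feature modality."""
        y = np.array([1.0, 1.0, -1.0, -1.0])
        K_signal = np.outer(y, y) + 1e-6 * np.eye(4)
        K_zero = 1e-12 * np.eye(4)
        model = easymkl_fit(_kernel_set_from_arrays([K_signal, K_zero]), y, 0.1)
        assert model.eta[0] == pytest.approx(1.0, abs=1e-6)
        assert model.eta[1] == pytest.approx(0.0, abs=1e-6)

    def test_eta_equivariant_under_modality_permutation(self, rng):
        Ks = []
        for _ in range(3):
            X = rng.standard_normal((8, 4))
            Ks.append(X @ X.T)
        y = np.array([1.0] * 4 + [-1.0] * 4)
        m1 = easymkl_fit(_kernel_set_from_arrays(Ks), y, 0.1)
        m2 = easymkl_fit(_kernel_set_from_arrays(Ks[::-1]), y, 0.1)
        assert np.allclose(m1.eta, m2.eta[::-1], atol=1e-8)

    def test_eta_invariant_to_common_kernel_scaling(self, rng):
        # tested at lam=0: the ridge term is the one part of the objective
        # that is not homogeneous in the kernel scale
        Ks = []
        for _ in range(2):
            X = rng.standard_normal((6, 4))
            Ks.append(X @ X.T)
        y = np.array([1.0] * 3 + [-1.0] * 3)
        m1 = easymkl_fit(_kernel_set_from_arrays(Ks), y, 0.0)
        m2 = easymkl_fit(_kernel_set_from_arrays([3.0 * K for K in Ks]), y, 0.0)
        assert np.allclose(m1.eta, m2.eta, atol=1e-8)

    def test_empty_kernel_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            easymkl_fit(KernelSet([]), np.array([1.0, -1.0]), 0.1)

    def test_all_zero_kernels_raise_degenerate(self):
        y = np.array([1.0, -1.0])
        with pytest.raises(ValueError, match="degenerate"):
            easymkl_fit(_kernel_set_from_arrays([np.zeros((2, 2))]), y, 0.1)


class TestDecisionScores:
    def _toy_model(self, bias=0.0):
        return MKLModel(
            eta=np.array([1.0]),
            gamma=np.array([1.0, 1.0]),
            lambda_reg=0.1,
            bias=bias,
            train_subjects=("s0", "s1"),
            labels=np.array([1.0, -1.0]),
            modality_names=("m0",),
            kernel_scales=(1.0,),
        )

    def _test_kernel_set(self, test_block):
        ids = ("s0", "s1")
        ktr = GramMatrix(np.eye(2), ids, ids, "m0")
        kte = GramMatrix(np.asarray(test_block, float), ("t0",), ids, "m0")
        return KernelSet([("m0", ktr, kte)])

    def test_zero_test_kernel_scores_equal_bias(self):
        model = self._toy_model(bias=0.7)
        scores = mkl_decision_scores(model, self._test_kernel_set([[0.0, 0.0]]))
        assert np.allclose(scores, [0.7])

    def test_hand_evaluated_score(self):
        # score = 1*(+1)*1 + 1*(-1)*0 + bias
        model = self._toy_model(bias=0.25)
        scores = mkl_decision_scores(model, self._test_kernel_set([[1.0, 0.0]]))
        assert scores[0] == pytest.approx(1.25)

    def test_modality_mismatch_raises(self):
        model = self._toy_model()
        kset = self._test_kernel_set([[1.0, 0.0]])
        kset.entries[0] = ("other", *kset.entries[0][1:])
        with pytest.raises(ValueError, match="mismatch"):
            mkl_decision_scores(model, kset)


class TestPrimalDual:
    @pytest.mark.parametrize("seed", range(5))
    def test_kernel_and_primal_scores_agree(self, seed):
        spec = SyntheticSpec(
            n_pos=7, n_neg=9, modality_dims=(5, 12, 8), effect_size=0.8, seed=seed
        )
        ds = generate_cohort(spec)
        tr, te = np.arange(12), np.arange(12, 16)
        kset = build_kernel_set(ds, tr, te)
        model = easymkl_fit(kset, ds.labels[tr], 0.1)
        s_kernel = mkl_decision_scores(model, kset)
        w = extract_primal_weights(model, {m.name: m.X[tr] for m in ds.modalities})
        s_primal = sum(ds.modality(n).X[te] @ w[n] for n in w) + model.bias
        assert np.max(np.abs(s_kernel - s_primal)) <= 1e-8

    def test_zero_eta_modality_has_zero_weights(self):
        y = np.array([1.0, 1.0, -1.0, -1.0])
        K_signal = np.outer(y, y) + 1e-6 * np.eye(4)
        kset = _kernel_set_from_arrays([K_signal, np.zeros((4, 4)) + 1e-12 * np.eye(4)])
        model = easymkl_fit(kset, y, 0.1)
        feats = {"m0": np.eye(4), "m1": np.eye(4)}
        w = extract_primal_weights(model, feats)
        assert np.max(np.abs(w["m1"])) <= 1e-6

    def test_row_count_mismatch_raises(self, rng):
        X = rng.standard_normal((6, 3))
        kset = _kernel_set_from_arrays([X @ X.T])
        y = np.array([1.0] * 3 + [-1.0] * 3)
        model = easymkl_fit(kset, y, 0.1)
        with pytest.raises(ValueError, match="row count"):
            extract_primal_weights(model, {"m0": X[:4]})


def test_model_json_round_trip(rng):
    X = rng.standard_normal((6, 3))
    kset = _kernel_set_from_arrays([X @ X.T])
    y = np.array([1.0] * 3 + [-1.0] * 3)
    model = easymkl_fit(kset, y, 0.1)
    restored = MKLModel.from_json(model.to_json())
    assert np.allclose(restored.eta, model.eta)
    assert np.allclose(restored.gamma, model.gamma)
    assert restored.bias == model.bias
    assert restored.train_subjects == model.train_subjects


def test_single_kernel_composite_ranks_like_komd(rng):
    """With one kernel the two-stage fit must reduce to plain KOMD scoring."""
    X = rng.standard_normal((10, 4))
    Xte = rng.standard_normal((4, 4))
    y = np.array([1.0] * 5 + [-1.0] * 5)
    ids = tuple(f"s{i}" for i in range(10))
    ids_te = tuple(f"t{i}" for i in range(4))
    K = GramMatrix(X @ X.T, ids, ids, "m0")
    Kte = GramMatrix(Xte @ X.T, ids_te, ids, "m0")
    kset = KernelSet([("m0", K, Kte)])
    model = easymkl_fit(kset, y, 0.1)
    s_mkl = mkl_decision_scores(model, kset)
    g = solve_komd(K, y, 0.1)
    s_komd = (Xte @ X.T) @ (g * y)
    assert np.array_equal(np.argsort(s_mkl), np.argsort(s_komd))
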