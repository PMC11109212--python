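"""Tests of splitting, AUC metrics, permutation significance and the runner."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mklfusion import (
    SyntheticSpec,
    generate_cohort,
    make_splits,
    permutation_pvalue,
    pr_auc,
    roc_auc,
    run_experiment,
)


class TestMakeSplits:
    def test_balanced_even_counts(self):
        y = np.array([1.0] * 4 + [-1.0] * 4)
        plans = make_splits(y, 10, 0.75, 0)
        for p in plans:
            tr = y[list(p.train_idx)]
            te = y[list(p.test_idx)]
            assert (tr == 1).sum() == 3 and (tr == -1).sum() == 3
            assert (te == 1).sum() == 1 and (te == -1).sum() == 1

    def test_round_half_up_on_odd_class_sizes(self):
        # 11 positives at 0.75 -> round(8.25) = 8; 32 negatives -> 24
        y = np.array([1.0] * 11 + [-1.0] * 32)
        plans = make_splits(y, 5, 0.75, 0)
        for p in plans:
            tr = y[list(p.train_idx)]
            assert (tr == 1).sum() == 8
            assert (tr == -1).sum() == 24

    def test_deterministic_given_master_seed(self):
        y = np.array([1.0] * 6 + [-1.0] * 6)
        a = make_splits(y, 8, 0.75, 123)
        b = make_splits(y, 8, 0.75, 123)
        assert [p.train_idx for p in a] == [p.train_idx for p in b]

    def test_splits_differ_across_split_ids(self):
        y = np.array([1.0] * 10 + [-1.0] * 10)
        plans = make_splits(y, 20, 0.75, 0)
        assert len({p.train_idx for p in plans}) > 1

    def test_partition_covers_all_subjects(self):
        y = np.array([1.0] * 7 + [-1.0] * 9)
        for p in make_splits(y, 5, 0.6, 3):
            assert sorted(p.train_idx + p.test_idx) == list(range(16))

    def test_degenerate_class_raises(self):
        y = np.array([1.0, 1.0, -1.0, -1.0])
        with pytest.raises(ValueError, match="empty"):
            make_splits(y, 3, 0.9, 0)  # round(1.8)=2 -> empty test set


def _brute_force_auc(scores, labels):
    pos = scores[labels > 0]
    neg = scores[labels <= 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([2, 1], [1, -1], 1.0),
            ([0.9, 0.8, 0.7, 0.6], [1, -1, 1, -1], 0.75),
            ([1, 1, 1, 1], [1, -1, 1, -1], 0.5),
        ],
    )
    def test_worked_examples(self, scores, labels, expected):
        assert roc_auc(np.array(scores, float), np.array(labels)) == expected

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_equals_all_pairs_count(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        n_pos = int(rng.integers(1, n - 1))
        labels = np.array([1] * n_pos + [-1] * (n - n_pos))
        # discretized scores so ties actually occur
        scores = np.round(rng.standard_normal(n), 1)
        assert roc_auc(scores, labels) == pytest.approx(
            _brute_force_auc(scores, labels)
        )

    def test_monotone_transform_invariance(self, rng):
        scores = rng.standard_normal(30)
        labels = np.array([1] * 12 + [-1] * 18)
        assert roc_auc(np.exp(scores), labels) == roc_auc(scores, labels)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="class"):
            roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))


class TestPrAuc:
    def test_perfect_ranking_is_one(self):
        assert pr_auc(np.array([3.0, 2.0, 1.0]), np.array([1, 1, -1])) == 1.0

    def test_single_positive_ranked_first(self):
        scores = np.array([5.0, 1.0, 0.5, 0.2])
        labels = np.array([1, -1, -1, -1])
        assert pr_auc(scores, labels) == 1.0

    def test_random_scores_approach_prevalence(self, rng):
        n = 4000
        labels = np.array([1] * 1000 + [-1] * 3000)
        val = pr_auc(rng.standard_normal(n), labels)
        assert val == pytest.approx(0.25, abs=0.05)

    def test_trapezoid_variant_close_to_step(self, rng):
        scores = rng.standard_normal(60)
        labels = np.array([1] * 20 + [-1] * 40)
        a = pr_auc(scores, labels, method="step")
        b = pr_auc(scores, labels, method="trapezoid")
        assert abs(a - b) < 0.1

    def test_no_positive_raises(self):
        with pytest.raises(ValueError, match="positive"):
            pr_auc(np.array([1.0, 2.0]), np.array([-1, -1]))


class TestPermutationPvalue:
    def _splits(self, rng, n_splits=6, n=12):
        scores = [rng.standard_normal(n) for _ in range(n_splits)]
        labels = [np.array([1] * 4 + [-1] * 8) for _ in range(n_splits)]
        return scores, labels

    def test_floor_when_observed_beats_all(self, rng):
        scores, labels = self._splits(rng)
        p = permutation_pvalue(2.0, scores, labels, 999, 0)
        assert p == pytest.approx(1 / 1000)

    def test_ceiling_when_observed_below_all(self, rng):
        scores, labels = self._splits(rng)
        p = permutation_pvalue(-np.inf, scores, labels, 99, 0)
        assert p == 1.0

    def test_deterministic_given_seed(self, rng):
        scores, labels = self._splits(rng)
        assert permutation_pvalue(0.55, scores, labels, 49, 7) == permutation_pvalue(
            0.55, scores, labels, 49, 7
        )

    def test_zero_permutations_raises(self, rng):
        scores, labels = self._splits(rng)
        with pytest.raises(ValueError):
            permutation_pvalue(0.5, scores, labels, 0, 0)

    def test_null_pvalues_super_uniform(self, rng):
        """Under a true null the p-value distribution must not be
        anti-conservative at any level (resolution 1/(B+1))."""
        pvals = []
        for rep in range(300):
            scores = [rng.standard_normal(10) for _ in range(8)]
            labels = [np.array([1] * 4 + [-1] * 6) for _ in range(8)]
            obs = float(np.median([roc_auc(s, l) for s, l in zip(scores, labels)]))
            pvals.append(permutation_pvalue(obs, scores, labels, 99, int(rng.integers(2**31))))
        pvals = np.array(pvals)
        for alpha in (0.01, 0.05, 0.1, 0.25, 0.5):
            assert (pvals <= alpha).mean() <= alpha + 0.05


class TestRunExperiment:
    def test_end_to_end_determinism(self, tiny_dataset, fast_config):
        cfg = fast_config(master_seed=5)
        r1, a1 = run_experiment(tiny_dataset, ["unimodal", "mkl"], cfg)
        r2, a2 = run_experiment(tiny_dataset, ["unimodal", "mkl"], cfg)
        for name in r1:
            assert np.array_equal(r1[name].per_split_auc, r2[name].per_split_auc)
            assert r1[name].perm_pvalue == r2[name].perm_pvalue
        for e1, e2 in zip(a1.eta_per_split, a2.eta_per_split):
            assert np.array_equal(e1, e2)

    def test_all_families_run_and_share_splits(self, tiny_dataset, fast_config):
        cfg = fast_config()
        res, arch = run_experiment(
            tiny_dataset, ["unimodal", "early_fusion", "mkl", "stacking"], cfg
        )
        n_mod = len(tiny_dataset.modality_names)
        assert len(res) == n_mod + 3
        for r in res.values():
            assert len(r.per_split_auc) == cfg.n_splits
            assert r.perm_pvalue >= 1 / (cfg.n_permutations + 1)
            assert r.config_hash == cfg.config_hash()

    def test_unknown_model_spec_raises(self, tiny_dataset, fast_config):
        with pytest.raises(ValueError, match="unknown model spec"):
            run_experiment(tiny_dataset, ["deep_net"], fast_config())

    def test_exclusion_limits_mkl_modalities(self, tiny_dataset, fast_config):
        drop = tiny_dataset.modality_names[-1]
        cfg = fast_config(exclude_modalities=[drop])
        _, arch = run_experiment(tiny_dataset, ["mkl"], cfg)
        assert drop not in arch.mkl_modalities
        assert len(arch.eta_per_split[0]) == len(tiny_dataset.modality_names) - 1

    def test_svm_on_composite_kernel_variant(self, tiny_dataset, fast_config):
        """The alternative final classifier (hinge SVM on the precomputed
        composite kernel) runs end to end and archives per-modality weights."""
        cfg = fast_config(final_classifier="svm")
        res, arch = run_experiment(tiny_dataset, ["mkl"], cfg)
        assert len(res["mkl"].per_split_auc) == cfg.n_splits
        for mod in arch.mkl_modalities:
            assert len(arch.weights[("mkl", mod)]) == cfg.n_splits

    def test_null_datasets_keep_models_near_chance_on_average(self):
        """A single small null cohort can carry sizable chance separation, so
        the chance-level band is asserted on the across-cohort median, with a
        loose per-cohort sanity band."""
        from mklfusion import RunConfig

        per_cohort = []
        for seed in range(5):
            spec = SyntheticSpec(
                n_pos=15, n_neg=15, modality_dims=(6, 10), effect_size=0.0, seed=seed
            )
            ds = generate_cohort(spec)
            cfg = RunConfig(n_splits=25, n_permutations=1, master_seed=seed)
            res, _ = run_experiment(ds, ["early_fusion", "mkl"], cfg)
            for name, r in res.items():
                assert 0.2 <= r.median_auc <= 0.8, (seed, name)
            per_cohort.append(np.mean([r.median_auc for r in res.values()]))
        assert 0.35 <= float(np.median(per_cohort)) <= 0.65
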