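"""Monte-Carlo cross-validation, AUC metrics, and permutation significance.

The evaluation protocol is repeated random stratified splitting: ``n_splits``
(default 100) independent draws of a 75%/25% train/test partition that keeps
each class's proportion constant, the same splits shared across every model
family so comparisons are paired.  Performance is the median across splits of
the test-set ROC AUC; significance comes from a permutation null in which
each split's test labels are shuffled, the median AUC recomputed, and the
p-value taken as ``(1 + #{null >= observed}) / (B + 1)``.

Per-class train counts use round-half-up of ``train_frac * class_size``
(e.g. 11 positives at 0.75 -> 8 in train), which is deterministic and as
close to "same proportion in each set" as integer counts allow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, precision_recall_curve
from sklearn.svm import SVC

from .baselines import (
    concat_features,
    fit_linear_svm,
    linear_scores,
    stacked_generalization_fit,
    stacked_scores,
    zscore_train,
)
from .config import RunConfig, substream_seed
from .kernels import build_kernel_set
from .mkl import MKLModel, easymkl_fit, extract_primal_weights, mkl_decision_scores
from .synthetic import MultimodalDataset

__all__ = [
    "SplitPlan",
    "EvalResult",
    "ExperimentArchive",
    "make_splits",
    "roc_auc",
    "pr_auc",
    "permutation_pvalue",
    "run_experiment",
]


@dataclass(frozen=True)
class SplitPlan:
    split_id: int
    seed: int
    train_idx: tuple[int, ...]
    test_idx: tuple[int, ...]
    stratified: bool = True

    def __post_init__(self) -> None:
        if set(self.train_idx) & set(self.test_idx):
            raise ValueError(f"split {self.split_id}: train/test overlap")


@dataclass
class EvalResult:
    model_name: str
    per_split_auc: np.ndarray
    median_auc: float
    pr_auc_median: float
    perm_pvalue: float
    n_permutations: int
    config_hash: str

    def __post_init__(self) -> None:
        self.per_split_auc = np.asarray(self.per_split_auc, dtype=float)
        if np.any(self.per_split_auc < 0) or np.any(self.per_split_auc > 1):
            raise ValueError("AUC outside [0, 1]")
        if abs(self.median_auc - float(np.median(self.per_split_auc))) > 1e-12:
            raise ValueError("median_auc is not the median of per_split_auc")
        if not self.perm_pvalue >= 1.0 / (self.n_permutations + 1):
            raise ValueError("p-value below the add-one floor")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def make_splits(
    labels: np.ndarray,
    n_splits: int,
    train_frac: float,
    master_seed: int,
) -> list[SplitPlan]:
    """Stratified Monte-Carlo splits, one independent draw per split.

    Each split samples round-half-up(train_frac * class size) subjects per
    class into train, without replacement, from a seed derived from
    ``master_seed`` and the split index.
    """
    y = np.asarray(labels)
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    per_class_idx = {c: np.flatnonzero(y == c) for c in classes}
    for c, idx in per_class_idx.items():
        n_tr = _round_half_up(train_frac * idx.size)
        if n_tr == 0 or n_tr == idx.size:
            raise ValueError(
                f"class {c}: {idx.size} subjects give an empty train or test set "
                f"at train_frac={train_frac}"
            )
    plans = []
    for s in range(n_splits):
        seed = substream_seed(master_seed, "splits", s)
        rng = np.random.default_rng(seed)
        train: list[int] = []
        for c in classes:
            idx = per_class_idx[c]
            n_tr = _round_half_up(train_frac * idx.size)
            chosen = rng.choice(idx, size=n_tr, replace=False)
            train.extend(int(i) for i in chosen)
        train_set = set(train)
        test = [int(i) for i in range(len(y)) if i not in train_set]
        plans.append(
            SplitPlan(split_id=s, seed=seed, train_idx=tuple(sorted(train)), test_idx=tuple(test))
        )
    return plans


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC as the Mann-Whitney statistic.

    Equals (concordant pairs + 0.5 * tied pairs) / (n_pos * n_neg); tied
    scores receive half credit via midranks.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = y > 0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(s)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def pr_auc(scores: np.ndarray, labels: np.ndarray, method: str = "step") -> float:
    """Area under the precision-recall curve.

    ``step`` (default): the standard step-wise sum — precision at each
    distinct recall increment weighted by the recall step (average
    precision).  ``trapezoid``: trapezoidal integration of the same curve.
    Perfect ranking gives 1.0; uninformative scores approach the class
    prevalence.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if int((y > 0).sum()) == 0:
        raise ValueError("PR-AUC requires at least one positive label")
    if method == "step":
        return float(average_precision_score((y > 0).astype(int), s))
    if method == "trapezoid":
        precision, recall, _ = precision_recall_curve((y > 0).astype(int), s)
        order = np.argsort(recall)
        return float(np.trapezoid(precision[order], recall[order]))
    raise ValueError(f"unknown PR-AUC method {method!r}")


def permutation_pvalue(
    observed_median_auc: float,
    split_scores: list[np.ndarray],
    split_labels: list[np.ndarray],
    n_permutations: int,
    seed: int,
) -> float:
    """Permutation p-value for a median-across-splits AUC.

    Each replicate independently permutes every split's test labels and
    recomputes the median AUC; the p-value is the add-one estimator
    ``(1 + #{null >= observed}) / (B + 1)``, so it is never exactly zero.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if len(split_scores) != len(split_labels) or not split_scores:
        raise ValueError("need matching, nonempty score/label lists")
    rng = np.random.default_rng(seed)
    # Permuting labels over fixed scores = drawing which rank positions are
    # positive; precompute midranks once per split.
    ranks, n_pos, n_neg = [], [], []
    for s, y in zip(split_scores, split_labels):
        y = np.asarray(y)
        p = int((y > 0).sum())
        n = int((y <= 0).sum())
        if p == 0 or n == 0:
            raise ValueError("every split must contain both classes")
        ranks.append(rankdata(np.asarray(s, dtype=float)))
        n_pos.append(p)
        n_neg.append(n)
    nulls = np.empty(n_permutations)
    n_splits = len(split_scores)
    aucs = np.empty(n_splits)
    for b in range(n_permutations):
        for k in range(n_splits):
            perm = rng.permutation(len(ranks[k]))
            pos_ranks = ranks[k][perm[: n_pos[k]]]
            u = pos_ranks.sum() - n_pos[k] * (n_pos[k] + 1) / 2.0
            aucs[k] = u / (n_pos[k] * n_neg[k])
        nulls[b] = np.median(aucs)
    count = int(np.sum(nulls >= observed_median_auc))
    return float((1 + count) / (n_permutations + 1))


@dataclass
class ExperimentArchive:
    """Per-split artifacts of one experiment, keyed by config hash."""

    config_hash: str
    master_seed: int
    splits: list[SplitPlan]
    scores: dict[str, list[np.ndarray]] = field(default_factory=dict)
    test_labels: list[np.ndarray] = field(default_factory=list)
    weights: dict[tuple[str, str], list[np.ndarray]] = field(default_factory=dict)
    feature_labels: dict[str, tuple[str, ...]] = field(default_factory=dict)
    eta_per_split: list[np.ndarray] = field(default_factory=list)
    mkl_modalities: tuple[str, ...] = ()


def _expand_model_specs(model_specs: list[str], dataset: MultimodalDataset) -> list[str]:
    out = []
    valid = {"unimodal", "early_fusion", "mkl", "stacking"}
    for spec_name in model_specs:
        if spec_name == "unimodal":
            out.extend(f"unimodal:{m}" for m in dataset.modality_names)
        elif spec_name.startswith("unimodal:"):
            name = spec_name.split(":", 1)[1]
            dataset.modality(name)  # raises on unknown
            out.append(spec_name)
        elif spec_name in valid:
            out.append(spec_name)
        else:
            raise ValueError(f"unknown model spec {spec_name!r}; valid: {sorted(valid)}")
    return out


def _fit_mkl_split(
    dataset: MultimodalDataset,
    plan: SplitPlan,
    include: list[str],
    config: RunConfig,
) -> tuple[np.ndarray, MKLModel, dict[str, np.ndarray]]:
    """Fit the kernel-combination model on one split; return test scores,
    the model, and per-modality primal weights."""
    tr = np.asarray(plan.train_idx)
    te = np.asarray(plan.test_idx)
    kset = build_kernel_set(
        dataset, tr, te, include,
        normalization=config.kernel_normalization,
        standardize=config.standardize_kernel_features,
    )
    y_tr = dataset.labels[tr]
    model = easymkl_fit(kset, y_tr, config.lambda_reg)
    if config.final_classifier == "svm":
        # alternative reading of "provided to a SVM": hinge-loss SVM on the
        # precomputed composite kernel instead of re-solving KOMD
        Ks = np.asarray(kset.train_grams())
        K_comp = np.einsum("r,rij->ij", model.eta, Ks)
        clf = SVC(kernel="precomputed", C=config.C)
        clf.fit(K_comp, y_tr)
        K_test = np.einsum("r,rij->ij", model.eta, np.asarray(kset.test_grams()))
        sign = 1.0 if clf.classes_[1] > 0 else -1.0
        scores = sign * clf.decision_function(K_test)
        coeff = np.zeros(len(tr))
        coeff[clf.support_] = sign * clf.dual_coef_.ravel()
        weights = {}
        for r, name in enumerate(model.modality_names):
            if config.standardize_kernel_features:
                Xtr, _ = zscore_train(dataset.modality(name).X[tr])
            else:
                Xtr = dataset.modality(name).X[tr]
            weights[name] = model.eta[r] * model.kernel_scales[r] * (Xtr.T @ coeff)
        return scores, model, weights
    scores = mkl_decision_scores(model, kset)
    feats = {}
    for name in model.modality_names:
        X = dataset.modality(name).X[tr]
        if config.standardize_kernel_features:
            X, _ = zscore_train(X)
        feats[name] = X
    weights = extract_primal_weights(model, feats)
    return scores, model, weights


def run_experiment(
    dataset: MultimodalDataset,
    model_specs: list[str],
    config: RunConfig,
) -> tuple[dict[str, EvalResult], ExperimentArchive]:
    """Evaluate the requested model families under shared Monte-Carlo splits.

    Families: ``unimodal`` (one linear SVM per modality, expanded
    automatically), ``early_fusion``, ``mkl``, ``stacking``.  The multimodal
    families use ``config.include_modalities`` (or all modalities minus
    ``config.exclude_modalities``); unimodal models always run on their own
    modality.  Per split, primal weight vectors per modality are archived for
    the stability analysis.  Everything is keyed by the config hash and the
    master seed.
    """
    models = _expand_model_specs(model_specs, dataset)
    include = (
        list(config.include_modalities)
        if config.include_modalities is not None
        else [m for m in dataset.modality_names if m not in config.exclude_modalities]
    )
    plans = make_splits(dataset.labels, config.n_splits, config.train_frac, config.master_seed)
    chash = config.config_hash()
    archive = ExperimentArchive(config_hash=chash, master_seed=config.master_seed, splits=plans)
    for m in dataset.modalities:
        archive.feature_labels[m.name] = m.feature_labels
    archive.mkl_modalities = tuple(include)
    for name in models:
        archive.scores[name] = []

    for plan in plans:
        tr = np.asarray(plan.train_idx)
        te = np.asarray(plan.test_idx)
        y_tr = dataset.labels[tr]
        y_te = dataset.labels[te]
        archive.test_labels.append(y_te)
        for name in models:
            if name.startswith("unimodal:"):
                mod = name.split(":", 1)[1]
                X = dataset.modality(mod).X
                Z_tr, Z_te = zscore_train(X[tr], X[te])
                lm = fit_linear_svm(Z_tr, y_tr, C=config.C)
                archive.scores[name].append(linear_scores(lm, Z_te))
                archive.weights.setdefault((name, mod), []).append(lm.weights)
            elif name == "early_fusion":
                X_all, _ = concat_features(
                    dataset, include, train_idx=tr, scale=config.scale_early_fusion
                )
                lm = fit_linear_svm(X_all[tr], y_tr, C=config.C)
                archive.scores[name].append(linear_scores(lm, X_all[te]))
                offset = 0
                for mod in include:
                    width = dataset.modality(mod).X.shape[1]
                    archive.weights.setdefault((name, mod), []).append(
                        lm.weights[offset : offset + width]
                    )
                    offset += width
            elif name == "mkl":
                scores, model, weights = _fit_mkl_split(dataset, plan, include, config)
                archive.scores[name].append(scores)
                archive.eta_per_split.append(model.eta)
                for mod, w in weights.items():
                    archive.weights.setdefault((name, mod), []).append(w)
            elif name == "stacking":
                meta, bases = stacked_generalization_fit(
                    dataset, tr, include,
                    inner_folds=config.stacking_inner_folds, C=config.C,
                    seed=substream_seed(config.master_seed, "stacking", plan.split_id),
                )
                archive.scores[name].append(
                    stacked_scores(meta, bases, dataset, tr, te, include)
                )

    perm_seed = substream_seed(config.master_seed, "permutations")
    results = {}
    for name in models:
        aucs = np.array(
            [roc_auc(s, yl) for s, yl in zip(archive.scores[name], archive.test_labels)]
        )
        pr = np.array(
            [pr_auc(s, yl) for s, yl in zip(archive.scores[name], archive.test_labels)]
        )
        med = float(np.median(aucs))
        pval = permutation_pvalue(
            med, archive.scores[name], archive.test_labels,
            config.n_permutations, perm_seed,
        )
        results[name] = EvalResult(
            model_name=name,
            per_split_auc=aucs,
            median_auc=med,
            pr_auc_median=float(np.median(pr)),
            perm_pvalue=pval,
            n_permutations=config.n_permutations,
            config_hash=chash,
        )
    return results, archive
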