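"""Weight-vector stability across Monte-Carlo splits.

Linear classifiers expose a feature-space weight vector per fit.  With small
cohorts and high-dimensional modalities those vectors can swing wildly
between train sets — a multi-stable pattern in which the learned "signature"
depends on which subjects happened to be sampled.  This module quantifies
and visualizes that variability: weight vectors from every split are
unit-normalized, projected to two dimensions with PCA for inspection, and
summarized by a dispersion statistic (mean pairwise cosine similarity; 1
means every split learned the same direction, near 0 means unrelated
directions).  Comparing the panels of a unimodal SVM against those of the
kernel-combination model per modality shows whether fusing modalities
stabilizes the learned patterns.

The PCA is fit jointly on all panels passed in together (so, e.g., SVM and
MKL panels for one modality share axes and are directly comparable).  The
dispersion statistic is this package's own quantitative summary of what the
2-D scatter shows; reports label it accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .evaluation import ExperimentArchive

__all__ = [
    "WeightPanel",
    "StabilityResult",
    "collect_weights",
    "pca_project",
    "dispersion",
    "top_features",
]


@dataclass
class WeightPanel:
    """Unit-normalized per-split weight vectors of one model on one modality."""

    modality: str
    model_name: str
    matrix: np.ndarray  # splits × features, rows unit-norm
    feature_labels: tuple[str, ...]
    split_seeds: tuple[int, ...]
    n_zero_rows_dropped: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("weight panel must be 2-D (splits × features)")
        if self.matrix.shape[1] != len(self.feature_labels):
            raise ValueError("feature label count does not match panel width")
        if self.matrix.shape[0] != len(self.split_seeds):
            raise ValueError("split seed count does not match panel rows")
        norms = np.linalg.norm(self.matrix, axis=1)
        if self.matrix.shape[0] and np.max(np.abs(norms - 1.0)) > 1e-10:
            raise ValueError("panel rows must be unit-norm")


@dataclass
class StabilityResult:
    coordinates: np.ndarray  # splits × 2
    explained_variance_fractions: tuple[float, float]
    dispersion: float
    fitted_on: tuple[str, ...]

    def __post_init__(self) -> None:
        e1, e2 = self.explained_variance_fractions
        if not (0.0 <= e2 <= e1 <= 1.0 and e1 + e2 <= 1.0 + 1e-12):
            raise ValueError(
                f"invalid explained-variance fractions {self.explained_variance_fractions}"
            )


def collect_weights(
    archive: ExperimentArchive, modality: str, model_name: str
) -> WeightPanel:
    """Stack one model's per-split weight vectors for one modality.

    Rows are unit-normalized; all-zero vectors (a modality assigned zero
    kernel weight in some split) cannot be normalized and are dropped with a
    warning, their count recorded on the panel.
    """
    key = (model_name, modality)
    if key not in archive.weights:
        have = sorted({f"{m}/{mod}" for m, mod in archive.weights})
        raise KeyError(f"no archived weights for model={model_name!r}, "
                       f"modality={modality!r}; have {have}")
    rows = np.vstack(archive.weights[key])
    seeds = np.array([p.seed for p in archive.splits[: rows.shape[0]]])
    norms = np.linalg.norm(rows, axis=1)
    keep = norms > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"{model_name}/{modality}: dropped {n_dropped} zero-norm weight vectors",
            stacklevel=2,
        )
    unit = rows[keep] / norms[keep, None]
    return WeightPanel(
        modality=modality,
        model_name=model_name,
        matrix=unit,
        feature_labels=tuple(archive.feature_labels[modality]),
        split_seeds=tuple(int(s) for s in seeds[keep]),
        n_zero_rows_dropped=n_dropped,
    )


def pca_project(panels: list[WeightPanel]) -> list[StabilityResult]:
    """Project weight panels to 2-D with a PCA fit on their union.

    Fitting once on the row-stacked union keeps the axes shared across
    panels (model families) so their scatters are comparable.  If the rows
    have zero variance the projection is the zero map and the explained
    variance fractions are reported as 0.
    """
    if not panels:
        raise ValueError("need at least one panel")
    labels0 = panels[0].feature_labels
    for p in panels:
        if p.feature_labels != labels0:
            raise ValueError(
                f"panels must share one feature space; {p.model_name}/{p.modality} differs"
            )
    stacked = np.vstack([p.matrix for p in panels])
    if stacked.shape[0] < 3:
        raise ValueError(f"need >= 3 rows total for a 2-D projection, got {stacked.shape[0]}")
    centered = stacked - stacked.mean(axis=0)
    total_var = float(np.sum(centered**2))
    fitted_on = tuple(f"{p.model_name}/{p.modality}" for p in panels)
    if total_var <= 1e-24:
        return [
            StabilityResult(
                coordinates=np.zeros((p.matrix.shape[0], 2)),
                explained_variance_fractions=(0.0, 0.0),
                dispersion=dispersion(p),
                fitted_on=fitted_on,
            )
            for p in panels
        ]
    pca = PCA(n_components=2, svd_solver="full")
    pca.fit(stacked)
    evf = tuple(float(v) for v in pca.explained_variance_ratio_)
    out = []
    for p in panels:
        out.append(
            StabilityResult(
                coordinates=pca.transform(p.matrix),
                explained_variance_fractions=evf,
                dispersion=dispersion(p),
                fitted_on=fitted_on,
            )
        )
    return out


def dispersion(panel: WeightPanel) -> float:
    """Mean pairwise cosine similarity across a panel's rows.

    1 = every split learned the same direction; values near 0 = unrelated
    directions.  Rows are already unit-norm, so the mean off-diagonal entry
    of ``M M'`` is the statistic; computed via the Gram identity
    ``(||sum rows||^2 - n) / (n (n - 1))``.
    """
    n = panel.matrix.shape[0]
    if n < 2:
        raise ValueError(f"dispersion needs >= 2 rows, got {n}")
    total = panel.matrix.sum(axis=0)
    return float((total @ total - n) / (n * (n - 1)))


def top_features(
    panel: WeightPanel, k: int
) -> list[tuple[str, float, float]]:
    """The k features with the largest mean absolute weight across splits.

    Returns (feature label, signed mean weight, mean absolute weight) in
    descending mean-|weight| order; a positive signed mean tilts the feature
    toward the positive-class label.  Ties in mean |weight| break by
    feature-label lexicographic order for determinism.
    """
    n_feat = panel.matrix.shape[1]
    if not 1 <= k <= n_feat:
        raise ValueError(f"k must be in [1, {n_feat}], got {k}")
    mean_abs = np.abs(panel.matrix).mean(axis=0)
    mean_signed = panel.matrix.mean(axis=0)
    order = sorted(
        range(n_feat), key=lambda j: (-mean_abs[j], panel.feature_labels[j])
    )
    return [
        (panel.feature_labels[j], float(mean_signed[j]), float(mean_abs[j]))
        for j in order[:k]
    ]
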