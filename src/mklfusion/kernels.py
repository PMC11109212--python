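"""Per-modality linear kernels: construction, normalization, leakage guards.

A kernel here is the subject-by-subject Gram matrix of dot products between
feature vectors.  Before combination, each modality's kernel is normalized so
that modalities of very different dimensionality (84 structural features next
to thousands of connectivity edges) contribute on a comparable scale.  The
default is trace normalization — scale the train-train block to trace
``n_train`` — which is the convention of the kernel-combination literature;
unit-diagonal (cosine) normalization is available as an alternative.  The
normalization constant is always computed from the train block only and then
applied to the test-train block, so no test information leaks into training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import MultimodalDataset

__all__ = ["GramMatrix", "KernelSet", "linear_kernel", "normalize_kernel", "build_kernel_set"]

_SYM_TOL = 1e-10
_PSD_TOL = 1e-8


@dataclass
class GramMatrix:
    """A (possibly rectangular) block of subject-by-subject dot products."""

    values: np.ndarray
    row_subjects: tuple[str, ...]
    col_subjects: tuple[str, ...]
    modality: str
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_subjects), len(self.col_subjects)):
            raise ValueError(
                f"modality {self.modality!r}: Gram shape {self.values.shape} does not "
                f"match subject lists ({len(self.row_subjects)}, {len(self.col_subjects)})"
            )
        if self.scale_factor <= 0:
            raise ValueError(f"scale_factor must be positive, got {self.scale_factor}")
        if self.is_square:
            asym = np.max(np.abs(self.values - self.values.T))
            if asym > _SYM_TOL * max(1.0, np.max(np.abs(self.values))):
                raise ValueError(f"modality {self.modality!r}: asymmetric Gram (dev {asym:.2e})")

    @property
    def is_square(self) -> bool:
        return self.row_subjects == self.col_subjects

    def check_psd(self) -> None:
        """Raise if the (square) Gram is not positive semidefinite."""
        w = np.linalg.eigvalsh(0.5 * (self.values + self.values.T))
        lo, hi = w[0], max(w[-1], 0.0)
        if lo < -_PSD_TOL * max(hi, 1.0):
            raise ValueError(
                f"modality {self.modality!r}: Gram not PSD (min eigenvalue {lo:.3e})"
            )


@dataclass
class KernelSet:
    """Per-modality train-train (and optionally test-train) Gram matrices
    sharing one train subject ordering."""

    entries: list[tuple[str, GramMatrix, GramMatrix | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [name for name, _, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate modality in KernelSet: {names}")
        if self.entries:
            train_order = self.entries[0][1].col_subjects
            test_order = None
            for name, ktr, kte in self.entries:
                if not ktr.is_square or ktr.col_subjects != train_order:
                    raise ValueError(f"modality {name!r}: train ordering mismatch")
                if kte is not None:
                    if kte.col_subjects != train_order:
                        raise ValueError(f"modality {name!r}: test block column mismatch")
                    if test_order is None:
                        test_order = kte.row_subjects
                    elif kte.row_subjects != test_order:
                        raise ValueError(f"modality {name!r}: test ordering mismatch")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def modality_names(self) -> list[str]:
        return [name for name, _, _ in self.entries]

    @property
    def train_subjects(self) -> tuple[str, ...]:
        return self.entries[0][1].col_subjects

    def train_grams(self) -> list[np.ndarray]:
        return [ktr.values for _, ktr, _ in self.entries]

    def test_grams(self) -> list[np.ndarray]:
        out = []
        for name, _, kte in self.entries:
            if kte is None:
                raise ValueError(f"modality {name!r}: no test block present")
            out.append(kte.values)
        return out

    def scale_factors(self) -> list[float]:
        return [ktr.scale_factor for _, ktr, _ in self.entries]


def linear_kernel(
    train_features: np.ndarray,
    test_features: np.ndarray | None = None,
    *,
    modality: str = "",
    train_subjects: tuple[str, ...] | None = None,
    test_subjects: tuple[str, ...] | None = None,
) -> tuple[GramMatrix, GramMatrix | None]:
    """Dot-product Gram matrices: train-train and, if given, test-train.

    Entry (i, j) of the train block is the dot product of subject i's and
    subject j's feature vectors; the test block pairs test rows with train
    columns.  ``scale_factor`` starts at 1 (no normalization applied yet).
    """
    Xtr = np.asarray(train_features, dtype=float)
    if Xtr.ndim != 2 or Xtr.shape[0] == 0:
        raise ValueError(f"train features must be a nonempty 2-D matrix, got shape {Xtr.shape}")
    if not np.all(np.isfinite(Xtr)):
        raise ValueError("train features contain non-finite values")
    ids_tr = train_subjects or tuple(f"T{i}" for i in range(Xtr.shape[0]))
    Ktr = GramMatrix(Xtr @ Xtr.T, ids_tr, ids_tr, modality)

    Kte = None
    if test_features is not None:
        Xte = np.asarray(test_features, dtype=float)
        if Xte.ndim != 2 or Xte.shape[1] != Xtr.shape[1]:
            raise ValueError(
                f"feature width mismatch: train {Xtr.shape[1]}, test "
                f"{Xte.shape[1] if Xte.ndim == 2 else '?'}"
            )
        if not np.all(np.isfinite(Xte)):
            raise ValueError("test features contain non-finite values")
        ids_te = test_subjects or tuple(f"U{i}" for i in range(Xte.shape[0]))
        Kte = GramMatrix(Xte @ Xtr.T, ids_te, ids_tr, modality)
    return Ktr, Kte


def normalize_kernel(
    train_gram: GramMatrix,
    test_gram: GramMatrix | None = None,
    *,
    method: str = "trace",
) -> tuple[GramMatrix, GramMatrix | None]:
    """Normalize a train kernel and apply the same transform to its test block.

    ``trace`` (default): multiply by ``c = n_train / trace`` so the train
    trace becomes exactly ``n_train``; ``c`` is recorded in ``scale_factor``
    for later primal-weight reconstruction.  ``unit_diagonal``: cosine
    normalization ``K_ij / sqrt(K_ii K_jj)`` (scale_factor stays 1 because
    the transform is not a global scalar).
    """
    if not train_gram.is_square:
        raise ValueError(f"modality {train_gram.modality!r}: train Gram must be square")
    K = train_gram.values
    n = K.shape[0]
    if method == "trace":
        tr = float(np.trace(K))
        if tr <= 0:
            raise ValueError(
                f"modality {train_gram.modality!r}: degenerate kernel (trace {tr:.3e})"
            )
        c = n / tr
        out_tr = GramMatrix(
            c * K, train_gram.row_subjects, train_gram.col_subjects,
            train_gram.modality, scale_factor=train_gram.scale_factor * c,
        )
        out_te = None
        if test_gram is not None:
            out_te = GramMatrix(
                c * test_gram.values, test_gram.row_subjects, test_gram.col_subjects,
                test_gram.modality, scale_factor=test_gram.scale_factor * c,
            )
        return out_tr, out_te
    if method == "unit_diagonal":
        diag = np.diag(K).copy()
        if np.any(diag <= 0):
            raise ValueError(
                f"modality {train_gram.modality!r}: zero-norm subject in cosine normalization"
            )
        s = 1.0 / np.sqrt(diag)
        out_tr = GramMatrix(
            K * np.outer(s, s), train_gram.row_subjects, train_gram.col_subjects,
            train_gram.modality, scale_factor=train_gram.scale_factor,
        )
        if test_gram is not None:
            # cross-block cosine normalization needs the test subjects' own
            # squared norms, which a test-train Gram does not contain
            raise NotImplementedError(
                "unit_diagonal normalization of test blocks requires test self-norms; "
                "use build_kernel_set, which computes them from the features"
            )
        return out_tr, None
    raise ValueError(f"unknown normalization method {method!r}")


def build_kernel_set(
    dataset: MultimodalDataset,
    train_idx: np.ndarray,
    test_idx: np.ndarray | None = None,
    include_modalities: list[str] | None = None,
    *,
    normalization: str = "trace",
    standardize: bool = False,
) -> KernelSet:
    """Normalized per-modality kernels for one train/test split.

    Normalization constants (and, with ``standardize``, the per-feature
    z-scoring statistics) are computed on train rows only.  Modalities not in
    ``include_modalities`` are omitted — the mechanism used to drop a
    chance-level modality from multimodal fusion.
    """
    train_idx = np.asarray(train_idx, dtype=int)
    include = include_modalities if include_modalities is not None else dataset.modality_names
    unknown = set(include) - set(dataset.modality_names)
    if unknown:
        raise KeyError(f"unknown modalities {sorted(unknown)}; have {dataset.modality_names}")
    if test_idx is not None:
        test_idx = np.asarray(test_idx, dtype=int)
        if np.intersect1d(train_idx, test_idx).size:
            raise ValueError("train/test leakage: index sets overlap")
    all_idx = np.concatenate([train_idx, test_idx]) if test_idx is not None else train_idx
    if all_idx.size and (all_idx.min() < 0 or all_idx.max() >= dataset.n_subjects):
        raise IndexError("subject index out of range")

    ids = np.asarray(dataset.subject_ids)
    ids_tr = tuple(ids[train_idx])
    ids_te = tuple(ids[test_idx]) if test_idx is not None else None

    entries = []
    for name in include:
        X = dataset.modality(name).X
        Xtr = X[train_idx]
        Xte = X[test_idx] if test_idx is not None else None
        if standardize:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd_safe = np.where(sd > 0, sd, 1.0)
            Xtr = np.where(sd > 0, (Xtr - mu) / sd_safe, 0.0)
            if Xte is not None:
                Xte = np.where(sd > 0, (Xte - mu) / sd_safe, 0.0)
        Ktr, Kte = linear_kernel(
            Xtr, Xte, modality=name, train_subjects=ids_tr, test_subjects=ids_te
        )
        if normalization == "unit_diagonal":
            # cosine-normalize feature rows directly: equivalent and leak-free,
            # since each subject is scaled by its own norm only
            norms_tr = np.sqrt(np.diag(Ktr.values))
            if np.any(norms_tr <= 0):
                raise ValueError(f"modality {name!r}: zero-norm train subject")
            Ktr = GramMatrix(
                Ktr.values / np.outer(norms_tr, norms_tr), ids_tr, ids_tr, name
            )
            if Kte is not None:
                norms_te = np.sqrt(np.einsum("ij,ij->i", Xte, Xte))
                if np.any(norms_te <= 0):
                    raise ValueError(f"modality {name!r}: zero-norm test subject")
                Kte = GramMatrix(
                    Kte.values / np.outer(norms_te, norms_tr), ids_te, ids_tr, name
                )
        else:
            Ktr, Kte = normalize_kernel(Ktr, Kte, method=normalization)
        entries.append((name, Ktr, Kte))
    return KernelSet(entries)
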