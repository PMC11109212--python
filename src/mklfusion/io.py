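"""Delimited-text readers and writers for cohorts, results and reports.

The interchange format is plain CSV throughout: one subjects-by-features
matrix per modality (header row of feature labels, first column the subject
ID), a two-column label file, and CSV/JSON result artifacts.  Every result
artifact embeds the hash of the configuration that produced it.  Subject
alignment across modality files uses the ID intersection — the complete-case
rule: a subject missing from any modality is dropped, and the drop is
reported.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import EvalResult, ExperimentArchive
from .stability import StabilityResult, WeightPanel
from .synthetic import Modality, MultimodalDataset

logger = logging.getLogger("mklfusion")

__all__ = [
    "write_cohort",
    "read_multimodal",
    "write_results_table",
    "write_archive_json",
    "write_coordinates",
    "write_rankings",
]


def write_cohort(
    dataset: MultimodalDataset, out_dir: str | Path, config_hash: str = ""
) -> dict[str, Path]:
    """Write one CSV per modality plus a label file; returns written paths.

    Matrices round-trip exactly: floats are serialized with full repr
    precision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for m in dataset.modalities:
        df = pd.DataFrame(m.X, columns=list(m.feature_labels))
        df.insert(0, "subject_id", list(dataset.subject_ids))
        path = out / f"{m.name}.csv"
        with open(path, "w") as fh:
            if config_hash:
                fh.write(f"# config_hash={config_hash}\n")
            df.to_csv(fh, index=False)
        paths[m.name] = path
    labels = pd.DataFrame(
        {"subject_id": list(dataset.subject_ids), "label": dataset.labels.astype(int)}
    )
    label_path = out / "labels.csv"
    with open(label_path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        labels.to_csv(fh, index=False)
    paths["labels"] = label_path
    return paths


def read_multimodal(
    modality_paths: dict[str, str | Path], label_path: str | Path
) -> MultimodalDataset:
    """Load modality CSVs and a label file into one aligned dataset.

    Subjects are aligned by the intersection of IDs across all files (in the
    label file's order); dropped subjects are logged per modality.  Labels
    may be coded {+1, -1}, {1, 0}, or {1, 2} and are mapped to {+1, -1}
    (larger value = positive class); more than two distinct values is an
    error.
    """
    ldf = pd.read_csv(label_path, comment="#", float_precision="round_trip")
    if ldf.shape[1] != 2:
        raise ValueError(f"label file must have two columns, got {list(ldf.columns)}")
    ldf.columns = ["subject_id", "label"]
    ids = ldf["subject_id"].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].tolist()
        raise ValueError(f"duplicate subject ids in label file: {dup}")
    values = sorted(ldf["label"].unique())
    if len(values) != 2:
        raise ValueError(f"labels must be binary, found values {values}")
    label_map = {values[1]: 1, values[0]: -1}

    frames: dict[str, pd.DataFrame] = {}
    common = set(ids)
    for name, path in modality_paths.items():
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        df = df.rename(columns={df.columns[0]: "subject_id"})
        df["subject_id"] = df["subject_id"].astype(str)
        if df["subject_id"].duplicated().any():
            raise ValueError(f"modality {name!r}: duplicate subject ids")
        if df.columns[1:].duplicated().any():
            raise ValueError(f"modality {name!r}: duplicate feature labels")
        frames[name] = df.set_index("subject_id")
        common &= set(df["subject_id"])
    if not common:
        raise ValueError("no subject appears in every file (empty ID intersection)")

    kept = [s for s in ids if s in common]
    for name, df in frames.items():
        dropped = sorted(set(df.index) - common)
        if dropped:
            logger.info("modality %s: dropping %d subjects absent elsewhere: %s",
                        name, len(dropped), dropped)
    dropped_lab = sorted(set(ids) - common)
    if dropped_lab:
        logger.info("label file: dropping %d subjects missing from some modality: %s",
                    len(dropped_lab), dropped_lab)

    labels = ldf.set_index(ids)["label"].loc[kept].map(label_map).to_numpy()
    modalities = []
    for name, df in frames.items():
        sub = df.loc[kept]
        X = sub.to_numpy(dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError(f"modality {name!r}: missing or non-finite values")
        modalities.append(
            Modality(name=name, X=X, feature_labels=tuple(str(c) for c in sub.columns))
        )
    return MultimodalDataset(
        subject_ids=tuple(kept), labels=labels.astype(float), modalities=tuple(modalities)
    )


def write_kernel(gram, path: str | Path) -> None:
    """Dump a Gram matrix as a square CSV with subject-ID headers."""
    df = pd.DataFrame(
        gram.values, index=list(gram.row_subjects), columns=list(gram.col_subjects)
    )
    df.to_csv(path, index_label="subject_id")


def write_results_table(
    results: dict[str, EvalResult], path: str | Path, config_hash: str
) -> None:
    """Model-by-metric summary table (median AUC, PR-AUC, permutation p)."""
    rows = [
        {
            "model": name,
            "median_auc": r.median_auc,
            "pr_auc_median": r.pr_auc_median,
            "perm_pvalue": r.perm_pvalue,
            "n_permutations": r.n_permutations,
        }
        for name, r in results.items()
    ]
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def write_archive_json(
    results: dict[str, EvalResult],
    archive: ExperimentArchive,
    path: str | Path,
) -> None:
    """Per-split AUCs, split seeds and kernel weights as a JSON archive."""
    doc = {
        "config_hash": archive.config_hash,
        "master_seed": archive.master_seed,
        "split_seeds": [p.seed for p in archive.splits],
        "splits": [
            {"split_id": p.split_id, "train_idx": list(p.train_idx), "test_idx": list(p.test_idx)}
            for p in archive.splits
        ],
        "per_split_auc": {name: r.per_split_auc.tolist() for name, r in results.items()},
        "median_auc": {name: r.median_auc for name, r in results.items()},
        "perm_pvalue": {name: r.perm_pvalue for name, r in results.items()},
        "mkl_modalities": list(archive.mkl_modalities),
        "eta_per_split": [e.tolist() for e in archive.eta_per_split],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def write_coordinates(
    panels: list[WeightPanel],
    stability: list[StabilityResult],
    path: str | Path,
    config_hash: str,
) -> None:
    """2-D PCA coordinates and dispersion per panel, one row per split.

    The dispersion column is this package's summary statistic (mean pairwise
    cosine similarity), not part of the original figure design.
    """
    rows = []
    for panel, res in zip(panels, stability):
        for i in range(panel.matrix.shape[0]):
            rows.append(
                {
                    "model": panel.model_name,
                    "modality": panel.modality,
                    "split_seed": panel.split_seeds[i],
                    "pc1": res.coordinates[i, 0],
                    "pc2": res.coordinates[i, 1],
                    "dispersion": res.dispersion,
                }
            )
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def write_rankings(
    ranked: list[tuple[str, float, float]], path: str | Path, config_hash: str
) -> None:
    """Top-feature table: label, signed mean weight, mean |weight|."""
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        pd.DataFrame(
            ranked, columns=["feature", "mean_weight", "mean_abs_weight"]
        ).to_csv(fh, index=False)
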