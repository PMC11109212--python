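"""Run configuration and seed management.

All randomness in the pipeline flows from a single master seed through named
substreams, so that simulation, split generation and permutation testing are
independently reproducible and adding one stage never perturbs another.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

# Stable identifiers for the named random substreams.  New stages must append,
# never renumber, or archived seeds lose their meaning.
_STREAMS = {
    "simulation": 0,
    "splits": 1,
    "permutations": 2,
    "stacking": 3,
    "models": 4,
}


def substream_seed(master_seed: int, stream: str, index: int = 0) -> int:
    """Derive a deterministic 31-bit seed for a named substream.

    Parameters
    ----------
    master_seed : int
        The experiment-level seed.
    stream : str
        One of ``simulation``, ``splits``, ``permutations``, ``stacking``,
        ``models``.
    index : int
        Optional within-stream index (e.g. split number).
    """
    if stream not in _STREAMS:
        raise KeyError(f"unknown substream {stream!r}; valid: {sorted(_STREAMS)}")
    ss = np.random.SeedSequence([int(master_seed), _STREAMS[stream], int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def substream_rng(master_seed: int, stream: str, index: int = 0) -> np.random.Generator:
    """A `numpy` Generator for a named substream of the master seed."""
    return np.random.default_rng(substream_seed(master_seed, stream, index))


@dataclass
class RunConfig:
    """Configuration of one end-to-end evaluation run.

    Attributes
    ----------
    modality_paths : dict mapping modality name to a delimited-text file, or
        empty when ``preset`` names a synthetic scenario.
    label_path : path of the two-column label file (ignored with a preset).
    preset : optional synthetic-scenario name
        (``chr_vs_control`` / ``converter_vs_nonconverter``).
    include_modalities / exclude_modalities : modality selection for the
        multimodal models (mirrors dropping a chance-level modality such as
        mean diffusivity from fusion).
    lambda_reg : EasyMKL regularization in [0, 1].
    C : SVM regularization strength.
    train_frac : train fraction of each Monte-Carlo split.
    n_splits : number of Monte-Carlo splits.
    n_permutations : label permutations for the significance test.
    master_seed : the single seed from which all substreams derive.
    kernel_normalization : ``trace`` (default) or ``unit_diagonal``.
    standardize_kernel_features : z-score features with train statistics
        before the dot product (off by default).
    scale_early_fusion : z-score features before concatenation (on by
        default).
    final_classifier : ``komd`` (default) or ``svm`` — what consumes the
        composite kernel.
    output_dir : where artifacts are written.
    """

    modality_paths: dict[str, str] = field(default_factory=dict)
    label_path: str | None = None
    preset: str | None = None
    include_modalities: list[str] | None = None
    exclude_modalities: list[str] = field(default_factory=list)
    lambda_reg: float = 0.1
    C: float = 1.0
    train_frac: float = 0.75
    n_splits: int = 100
    n_permutations: int = 1000
    master_seed: int = 0
    kernel_normalization: str = "trace"
    standardize_kernel_features: bool = False
    scale_early_fusion: bool = True
    final_classifier: str = "komd"
    stacking_inner_folds: int = 5
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.n_splits < 2:
            raise ValueError(f"n_splits must be >= 2, got {self.n_splits}")
        if self.n_permutations < 1:
            raise ValueError(f"n_permutations must be >= 1, got {self.n_permutations}")
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError(f"train_frac must be in (0, 1), got {self.train_frac}")
        if not 0.0 <= self.lambda_reg <= 1.0:
            raise ValueError(f"lambda_reg must be in [0, 1], got {self.lambda_reg}")
        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if self.kernel_normalization not in ("trace", "unit_diagonal"):
            raise ValueError(f"unknown kernel_normalization {self.kernel_normalization!r}")
        if self.final_classifier not in ("komd", "svm"):
            raise ValueError(f"unknown final_classifier {self.final_classifier!r}")
        if self.preset is None:
            for name, path in self.modality_paths.items():
                if not Path(path).exists():
                    raise FileNotFoundError(f"modality {name!r}: file not found: {path}")
            if self.modality_paths and (
                self.label_path is None or not Path(self.label_path).exists()
            ):
                raise FileNotFoundError(f"label file not found: {self.label_path}")

    def config_hash(self) -> str:
        """Stable short hash of every field that affects the computation."""
        d = asdict(self)
        d.pop("output_dir")
        payload = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a configuration from a JSON document."""
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)
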