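"""Synthetic gene-expression data with planted discriminative genes.

Microarray-style gene selection operates in the genes >> samples regime:
tens of samples, thousands of genes, of which only a handful carry class
signal.  The generator emulates exactly that structure so the whole wrapper
pipeline is testable without external downloads, and returns the planted
informative-gene indices as ground truth for recovery scoring.

Model: every gene is i.i.d. noise (Gaussian by default, Student-t optionally
since real expression data are heavy-tailed); an informative gene in class
``c`` has its mean shifted by ``c * delta`` noise standard deviations;
optional redundant genes are correlated copies (``rho``) of random
informative genes.  Labels are assigned round-robin, so class sizes are as
balanced as divisibility allows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gene_selection import ExpressionDataset

__all__ = [
    "SyntheticSpec",
    "generate",
    "write_dataset",
    "read_dataset",
    "write_truth",
    "read_truth",
    "DatasetFormatError",
    "NonNumericValueError",
    "MissingLabelColumnError",
]


class DatasetFormatError(ValueError):
    """Malformed expression-matrix file."""


class NonNumericValueError(DatasetFormatError):
    """A cell failed numeric parsing; carries row/column coordinates."""

    def __init__(self, row: int, column: str, value):
        self.row = row
        self.column = column
        self.value = value
        super().__init__(
            f"non-numeric value {value!r} at sample row {row}, gene column {column!r}"
        )


class MissingLabelColumnError(DatasetFormatError):
    """The expected label column is absent."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape and signal parameters of one synthetic dataset.

    ``class_shift`` is the between-class mean separation on informative
    genes in units of the noise standard deviation; 6 is well separated for
    1-NN, 0 makes every gene pure noise.
    """

    n_samples: int = 40
    n_genes: int = 500
    n_informative: int = 10
    n_classes: int = 2
    class_shift: float = 6.0
    noise_sd: float = 1.0
    n_redundant: int = 0
    redundancy_rho: float = 0.0
    noise: str = "gaussian"  # or "student_t"
    t_df: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 2:
            raise ValueError("need at least 2 samples and 1 gene")
        if not 0 <= self.n_informative <= self.n_genes:
            raise ValueError("n_informative must lie in [0, n_genes]")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.redundancy_rho < 1.0:
            raise ValueError("redundancy_rho must lie in [0, 1)")
        if self.n_redundant and not self.n_informative:
            raise ValueError("redundant genes need informative genes to copy")
        if self.n_informative + self.n_redundant > self.n_genes:
            raise ValueError("informative + redundant genes exceed n_genes")
        if self.noise not in {"gaussian", "student_t"}:
            raise ValueError("noise must be 'gaussian' or 'student_t'")


def _noise(rng: np.random.Generator, spec: SyntheticSpec, shape) -> np.ndarray:
    if spec.noise == "gaussian":
        return rng.normal(0.0, spec.noise_sd, shape)
    raw = rng.standard_t(spec.t_df, shape)
    # rescale so the marginal SD equals noise_sd (t has sd sqrt(df/(df-2)))
    return raw * spec.noise_sd / np.sqrt(spec.t_df / (spec.t_df - 2.0))


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, np.ndarray]:
    """Build one dataset; returns (dataset, sorted informative-gene indices).

    Deterministic given ``spec.seed`` — regeneration is byte-identical.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.n_genes
    labels = np.arange(n) % spec.n_classes
    matrix = _noise(rng, spec, (n, d))
    special = rng.choice(d, size=spec.n_informative + spec.n_redundant, replace=False)
    informative = np.sort(special[: spec.n_informative])
    redundant = np.sort(special[spec.n_informative :])
    shift = spec.class_shift * spec.noise_sd
    for g in informative:
        matrix[:, g] += labels * shift
    if redundant.size:
        sources = rng.choice(informative, size=redundant.size, replace=True)
        rho = spec.redundancy_rho
        matrix[:, redundant] = rho * matrix[:, sources] + np.sqrt(1.0 - rho**2) * matrix[
            :, redundant
        ]
    gene_ids = [f"gene_{i:05d}" for i in range(d)]
    dataset = ExpressionDataset(matrix, labels, gene_ids, name=f"synthetic-seed{spec.seed}")
    return dataset, informative


# ---------------------------------------------------------------------------
# delimited-text I/O (samples as rows, gene-id header, trailing label column)


def write_dataset(dataset: ExpressionDataset, path, label_column: str = "label") -> None:
    """Write as CSV with full float precision (lossless round trip)."""
    frame = pd.DataFrame(dataset.matrix, columns=dataset.gene_ids)
    frame[label_column] = dataset.labels
    frame.to_csv(path, index=False, float_format="%.17g")


def read_dataset(
    path, label_column: str = "label", name: str | None = None
) -> ExpressionDataset:
    """Load a delimited expression matrix; raises named errors on bad input."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DatasetFormatError(f"cannot parse {path}: {exc}") from exc
    if label_column not in frame.columns:
        raise MissingLabelColumnError(
            f"{path} has no {label_column!r} column (columns: {list(frame.columns)[:5]}...)"
        )
    labels = frame.pop(label_column).to_numpy()
    if frame.shape[1] < 1:
        raise DatasetFormatError(f"{path} contains no gene columns")
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        for i, cell in enumerate(frame[col].to_numpy()):
            try:
                # float() is a correctly rounded parser, so written values
                # round-trip bit for bit (pandas' fast parser does not)
                values[i, j] = float(cell)
            except (ValueError, TypeError):
                raise NonNumericValueError(i, col, cell) from None
            if np.isnan(values[i, j]):
                raise NonNumericValueError(i, col, cell)
    # labels stay integers when they parse as such
    try:
        labels = labels.astype(int)
    except (ValueError, TypeError):
        pass
    return ExpressionDataset(
        values, labels, list(frame.columns), name=name or path.stem
    )


def write_truth(informative: np.ndarray, path) -> None:
    """Sidecar ground truth: one informative gene index per line."""
    Path(path).write_text("\n".join(str(int(i)) for i in informative) + "\n")


def read_truth(path) -> np.ndarray:
    return np.array(
        [int(line) for line in Path(path).read_text().split() if line.strip()],
        dtype=int,
    )
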