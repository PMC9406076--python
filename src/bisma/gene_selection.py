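"""Wrapper gene selection: 1-NN leave-one-out error plus a subset-size penalty.

The wrapper objective scores a candidate gene subset by actually classifying
with it.  For a mask selecting ``DR`` of ``D`` genes the fitness is

    fit = alpha * LOOCV_error + beta * DR / D,        alpha + beta = 1,

with alpha = 0.95, beta = 0.05 by default, so classification error dominates
and the gene-count term breaks ties toward smaller subsets.  The classifier
is 1-nearest-neighbour with Euclidean distance under leave-one-out
cross-validation; distance ties are broken deterministically by the smallest
sample index, which makes every fitness value exactly reproducible.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .binarization import TransferFunctionSpec, run_bisma
from .core import ISMAParams, OptimizationResult

__all__ = [
    "ExpressionDataset",
    "FitnessWeights",
    "GeneSubset",
    "SelectionRunResult",
    "fitness",
    "nn_distance",
    "loocv_error",
    "SubsetEvaluator",
    "evaluate_subset",
    "select_genes",
    "summarize_runs",
]


@dataclass
class ExpressionDataset:
    """A samples x genes expression matrix with class labels.

    ``matrix`` rows are samples; ``labels`` is any hashable class coding;
    ``gene_ids`` names the columns.
    """

    matrix: np.ndarray
    labels: np.ndarray
    gene_ids: list[str]
    name: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.matrix.ndim != 2:
            raise ValueError("expression matrix must be 2-D (samples x genes)")
        n, d = self.matrix.shape
        if d < 1:
            raise ValueError("need at least one gene")
        if self.labels.shape != (n,):
            raise ValueError("labels must align with matrix rows")
        if np.isnan(self.matrix).any():
            raise ValueError("expression matrix contains missing values")
        classes, counts = np.unique(self.labels, return_counts=True)
        if classes.size < 2:
            raise ValueError("need at least 2 classes")
        if (counts < 2).any():
            import warnings

            warnings.warn(
                "some classes have fewer than 2 samples; leave-one-out error "
                "for those samples is forced",
                stacklevel=2,
            )
        if len(self.gene_ids) != d:
            raise ValueError("gene_ids must align with matrix columns")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def zscore(self) -> "ExpressionDataset":
        """Per-gene standardization (off by default in the pipeline)."""
        mu = self.matrix.mean(axis=0)
        sd = self.matrix.std(axis=0)
        sd[sd == 0] = 1.0
        return ExpressionDataset(
            (self.matrix - mu) / sd, self.labels, list(self.gene_ids), self.name
        )


@dataclass(frozen=True)
class FitnessWeights:
    """Error-vs-subset-size weighting; beta is tied to 1 - alpha."""

    alpha: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")

    @property
    def beta(self) -> float:
        return 1.0 - self.alpha


@dataclass
class GeneSubset:
    """A 0/1 inclusion mask over genes."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(np.int8)
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be 0/1")

    @property
    def size(self) -> int:
        return int(self.mask.sum())


def fitness(error_rate: float, dr: int, d: int, w: FitnessWeights = FitnessWeights()) -> float:
    """Weighted wrapper fitness ``alpha*error + beta*DR/D``."""
    if not 1 <= dr <= d:
        raise ValueError("selected-gene count must satisfy 1 <= DR <= D")
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must lie in [0, 1]")
    return w.alpha * error_rate + w.beta * dr / d


def nn_distance(x, y, literal: bool = False) -> float:
    """Distance between two expression profiles.

    Euclidean by default.  ``literal=True`` evaluates the non-metric
    sum-of-root-absolute-differences form for audit purposes only.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profile length mismatch")
    if literal:
        return float(np.sum(np.abs(x - y) ** 0.5))
    return float(np.sqrt(np.sum((x - y) ** 2)))


def loocv_error(dataset: ExpressionDataset, mask, k: int = 1) -> float:
    """Leave-one-out 1-NN misclassification fraction on the masked genes.

    Each sample is classified by the label of its nearest other sample;
    distance ties resolve to the smallest sample index.  Only k = 1 is
    supported (label ties cannot occur).
    """
    if k != 1:
        raise NotImplementedError("only the 1-nearest-neighbour rule is supported")
    mask = np.asarray(getattr(mask, "mask", mask)).astype(bool)
    if mask.shape != (dataset.n_genes,):
        raise ValueError("mask must have one entry per gene")
    if not mask.any():
        raise ValueError("mask selects no genes")
    n = dataset.n_samples
    if n < 2:
        raise ValueError("leave-one-out needs at least 2 samples")
    sub = dataset.matrix[:, mask]
    # explicit differences (not the Gram expansion) so squared distances are
    # computed exactly as in a direct double loop, ulp for ulp
    d2 = np.empty((n, n))
    for i in range(n):
        d2[i] = np.sum((sub - sub[i]) ** 2, axis=1)
    np.fill_diagonal(d2, np.inf)
    nearest = np.argmin(d2, axis=1)
    errors = dataset.labels[nearest] != dataset.labels
    return float(np.mean(errors))


class SubsetEvaluator:
    """Memoizing wrapper-fitness evaluator for one dataset and weighting.

    The cache is keyed on the packed mask bytes, so identical masks return
    bitwise-identical (error, fitness) pairs; ``n_evaluations`` counts cache
    misses only.
    """

    def __init__(
        self, dataset: ExpressionDataset, weights: FitnessWeights = FitnessWeights()
    ):
        self.dataset = dataset
        self.weights = weights
        self._cache: dict[bytes, tuple[float, float]] = {}
        self.n_evaluations = 0

    def __call__(self, mask) -> tuple[float, float]:
        mask = np.asarray(getattr(mask, "mask", mask)).astype(np.int8)
        key = np.packbits(mask).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        err = loocv_error(self.dataset, mask)
        fit = fitness(err, int(mask.sum()), self.dataset.n_genes, self.weights)
        self.n_evaluations += 1
        self._cache[key] = (err, fit)
        return err, fit

    def fitness_only(self, mask) -> float:
        return self(mask)[1]


def evaluate_subset(
    dataset: ExpressionDataset,
    mask,
    weights: FitnessWeights = FitnessWeights(),
    evaluator: SubsetEvaluator | None = None,
) -> tuple[float, float]:
    """(LOOCV error, wrapper fitness) of one mask; optionally memoized."""
    if evaluator is not None:
        return evaluator(mask)
    return SubsetEvaluator(dataset, weights)(mask)


@dataclass
class SelectionRunResult:
    """One independent gene-selection run."""

    mask: np.ndarray
    loocv_error: float
    fitness: float
    n_selected: int
    runtime: float
    seed: int
    history: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        return 1.0 - self.loocv_error


def select_genes(
    dataset: ExpressionDataset,
    tf: TransferFunctionSpec | str = "V4",
    params: ISMAParams | None = None,
    n_runs: int = 10,
    base_seed: int = 0,
    weights: FitnessWeights = FitnessWeights(),
    variant: str = "ISMA",
    shadow_bounds: tuple[float, float] = (0.0, 1.0),
) -> tuple[list[SelectionRunResult], pd.DataFrame]:
    """Run the binary optimizer ``n_runs`` times (seeds ``base_seed + i``).

    Default run settings follow the wrapper protocol: 50 iterations,
    20 search agents, 10 independent repeats.  Returns the per-run results
    and a one-row summary frame (mean/std of selected-gene count, error,
    fitness and runtime).
    """
    if params is None:
        params = ISMAParams(population_size=20, max_iter=50)
    results: list[SelectionRunResult] = []
    for run in range(n_runs):
        run_params = ISMAParams(
            **{
                **{f.name: getattr(params, f.name) for f in params.__dataclass_fields__.values()},
                "seed": base_seed + run,
            }
        )
        evaluator = SubsetEvaluator(dataset, weights)
        t0 = time.perf_counter()
        res = run_bisma(
            evaluator.fitness_only,
            dataset.n_genes,
            tf=tf,
            params=run_params,
            variant=variant,
            shadow_bounds=shadow_bounds,
        )
        elapsed = time.perf_counter() - t0
        err, fit = evaluator(res.best_bits)
        results.append(
            SelectionRunResult(
                mask=res.best_bits,
                loocv_error=err,
                fitness=fit,
                n_selected=int(res.best_bits.sum()),
                runtime=elapsed,
                seed=run_params.seed,
                history=res.history,
            )
        )
    return results, summarize_runs(results)


def summarize_runs(results: Sequence[SelectionRunResult]) -> pd.DataFrame:
    """Mean/std summary across independent runs (ddof=0 so one run gives 0)."""
    frame = pd.DataFrame(
        {
            "n_selected": [r.n_selected for r in results],
            "error": [r.loocv_error for r in results],
            "fitness": [r.fitness for r in results],
            "runtime": [r.runtime for r in results],
        }
    )
    out = {}
    for col in frame.columns:
        out[f"{col}_mean"] = frame[col].mean()
        out[f"{col}_std"] = frame[col].std(ddof=0)
    out["n_runs"] = len(results)
    return pd.DataFrame([out])


def runs_frame(results: Sequence[SelectionRunResult]) -> pd.DataFrame:
    """Per-run table (seed, n_selected, error, fitness, runtime) for export."""
    return pd.DataFrame(
        {
            "seed": [r.seed for r in results],
            "n_selected": [r.n_selected for r in results],
            "error": [r.loocv_error for r in results],
            "fitness": [r.fitness for r in results],
            "runtime": [r.runtime for r in results],
        }
    )
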