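"""Multi-seed experiment driver: run matrices and comparison reports."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import benchmarks
from .core import ISMAParams, run_isma
from .stats import friedman_mean_ranks, plus_equal_minus, wilcoxon_signed_rank

__all__ = ["RunMatrix", "run_matrix", "compare_report", "cell_seed"]


@dataclass
class RunMatrix:
    """A (methods x problems x repeats) experiment grid.

    ``methods`` are optimizer variant names ("SMA", "CSMA", "MCSMA",
    "ISMA"); ``problems`` are benchmark registry names.  Every cell runs
    with an independent seed derived from ``base_seed`` and the cell
    coordinates, so the grid is reproducible and cells are uncorrelated.
    """

    methods: list[str]
    problems: list[str]
    n_repeats: int = 30
    base_seed: int = 0
    params: ISMAParams = field(
        default_factory=lambda: ISMAParams(population_size=20, max_iter=50)
    )


def cell_seed(base_seed: int, method_idx: int, problem_idx: int, repeat: int) -> int:
    """Deterministic per-cell seed, kept below 2**31."""
    return (base_seed * 1000003 + method_idx * 9176 + problem_idx * 131 + repeat) % (
        2**31
    )


def run_matrix(matrix: RunMatrix) -> pd.DataFrame:
    """Execute the grid; rows are (method, problem, repeat, seed,
    best_fitness, n_evaluations)."""
    rows = []
    for mi, method in enumerate(matrix.methods):
        for pi, problem_name in enumerate(matrix.problems):
            for rep in range(matrix.n_repeats):
                seed = cell_seed(matrix.base_seed, mi, pi, rep)
                params = ISMAParams(
                    **{
                        **{
                            f.name: getattr(matrix.params, f.name)
                            for f in matrix.params.__dataclass_fields__.values()
                        },
                        "seed": seed,
                    }
                )
                noise_rng = np.random.default_rng(seed + 1)
                problem = benchmarks.make_problem(problem_name, rng=noise_rng)
                res = run_isma(problem, params, variant=method)
                rows.append(
                    {
                        "method": method,
                        "problem": problem_name,
                        "repeat": rep,
                        "seed": seed,
                        "best_fitness": res.best_fitness,
                        "n_evaluations": res.n_evaluations,
                    }
                )
    return pd.DataFrame(rows)


def compare_report(
    results: pd.DataFrame, reference: str | None = None, alpha: float = 0.05
) -> dict[str, pd.DataFrame]:
    """Comparison statistics from a run-matrix result frame.

    Returns ``{"arv": ..., "wilcoxon": ..., "labels": ...}``: Friedman mean
    ranks of per-(problem, repeat) best fitnesses, pairwise Wilcoxon tests of
    the reference method (first listed if not named) against every other
    method per problem, and the "+/=/-" counts per competitor.
    """
    methods = list(results["method"].unique())
    problems = list(results["problem"].unique())
    if reference is None:
        reference = methods[0]
    if reference not in methods:
        raise ValueError(f"reference {reference!r} not among methods {methods}")

    pivot = results.pivot_table(
        index=["problem", "repeat"], columns="method", values="best_fitness"
    )
    scores = pivot[methods].to_numpy().T  # methods x cases
    arv = pd.DataFrame({"method": methods, "arv": friedman_mean_ranks(scores)})

    wil_rows = []
    for other in methods:
        if other == reference:
            continue
        for problem in problems:
            sub = pivot.loc[problem]
            ref_vals = sub[reference].to_numpy()
            oth_vals = sub[other].to_numpy()
            res = wilcoxon_signed_rank(ref_vals, oth_vals)
            median_diff = float(np.median(ref_vals - oth_vals))
            direction = 0 if median_diff == 0 else (1 if median_diff < 0 else -1)
            wil_rows.append(
                {
                    "reference": reference,
                    "method": other,
                    "problem": problem,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "n_effective": res.n_effective,
                    "degenerate": res.degenerate,
                    "direction": direction,
                }
            )
    wilcoxon = pd.DataFrame(wil_rows)

    label_rows = []
    for other in methods:
        if other == reference:
            continue
        sub = wilcoxon[wilcoxon["method"] == other]
        plus, equal, minus = plus_equal_minus(
            sub["p_value"].to_numpy(), sub["direction"].to_numpy(), alpha
        )
        label_rows.append(
            {"reference": reference, "method": other, "plus": plus, "equal": equal, "minus": minus}
        )
    labels = pd.DataFrame(label_rows)
    return {"arv": arv, "wilcoxon": wilcoxon, "labels": labels}
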